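import numpy as np
import pytest

from strainvar import linear_models as lm
from strainvar.core_io import PWM
from strainvar.synth import SimulationConfig, simulate_expression


@pytest.fixture(scope="session")
def small_world():
    """Default-parameter synthetic panel, desk-sized (3,000 genes)."""
    X, truth = simulate_expression(SimulationConfig(n_genes=3000, seed=42))
    return X, truth


@pytest.fixture(scope="session")
def simple_fit(small_world):
    X, _ = small_world
    return lm.moderate(lm.fit_genewise(X, lm.build_design(X.samples, "simple")))


@pytest.fixture(scope="session")
def ahr_fit(small_world):
    X, _ = small_world
    return lm.moderate(lm.fit_genewise(X, lm.build_design(X.samples, "ancestry_ahr")))


@pytest.fixture()
def sharp_motif():
    """15-bp near-deterministic PWM (97:1:1:1 per column)."""
    consensus = "ACGTTGCAGCATTGA"
    counts = np.full((4, len(consensus)), 1.0)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 97.0
    return PWM("MA9001", "SHARP15", counts)
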