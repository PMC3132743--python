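"""Per-gene within/between-strain variance decomposition and the W/T ratio.

For each gene a one-way random-effects ANOVA over strains gives the pooled
within-strain variance W (mean square within) and the between-strain
component B = max(0, (MSB - W) / n0), with n0 the common replicate count in
the balanced case or its standard unbalanced analogue
(N - sum(n_i^2)/N) / (k - 1).  The ratio W/T with T = W + B measures how much
of a gene's variability is individual rather than strain-driven: 1 means all
variance is within strains (B truncated at zero), 0 means all between.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from strainvar.core_io import ExpressionMatrix

__all__ = ["partition_variance", "bin_by_intensity", "decile_groups"]

BIN_EDGES = (4.0, 8.0, 12.0)
BIN_LABELS = ("unexpressed", "low", "medium", "high")


def partition_variance(X: ExpressionMatrix) -> pd.DataFrame:
    """One-way ANOVA variance components per gene.

    Returns a DataFrame indexed by gene with columns ``W``, ``B``, ``T``,
    ``ratio``, ``mean_intensity``, ``bin``, ``decile`` and a boolean
    ``constant`` flag for zero-total-variance genes (reported with ratio 1).
    """
    strains = X.strains
    if len(strains) < 2:
        raise ValueError("need >= 2 strains for a variance partition")
    groups = []
    for st in strains:
        cols = X.strain_columns(st)
        if len(cols) < 2:
            raise ValueError(f"strain {st!r} has {len(cols)} replicate(s); need >= 2")
        groups.append(X.values[cols].to_numpy(dtype=float))

    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    N = int(ns.sum())
    grand = np.hstack(groups).mean(axis=1)
    group_means = np.column_stack([g.mean(axis=1) for g in groups])

    ss_within = sum(((g - g.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for g in groups)
    msw = ss_within / (N - k)
    ss_between = (ns[None, :] * (group_means - grand[:, None]) ** 2).sum(axis=1)
    msb = ss_between / (k - 1)
    n0 = (N - (ns**2).sum() / N) / (k - 1)

    W = msw
    B = np.maximum(0.0, (msb - msw) / n0)
    T = W + B
    constant = T <= 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(constant, 1.0, W / np.where(constant, 1.0, T))
    ratio = np.clip(ratio, 0.0, 1.0)

    out = pd.DataFrame(
        {
            "W": W,
            "B": B,
            "T": T,
            "ratio": ratio,
            "mean_intensity": grand,
            "constant": constant,
        },
        index=X.values.index,
    )
    out["bin"] = [bin_by_intensity(m) for m in grand]
    out["decile"] = decile_groups(out["ratio"].to_numpy())
    return out


def bin_by_intensity(mean_intensity: float) -> str:
    """Expression bin: <4 unexpressed, [4,8) low, [8,12) medium, >=12 high."""
    if not np.isfinite(mean_intensity):
        raise ValueError("mean intensity must be finite")
    idx = int(np.searchsorted(BIN_EDGES, mean_intensity, side="right"))
    return BIN_LABELS[idx]


def decile_groups(ratios) -> np.ndarray:
    """Ten equally spaced W/T groups: group k covers [(k-1)/10, k/10), with
    group 10 closed at 1.0."""
    r = np.asarray(ratios, dtype=float)
    if ((r < 0) | (r > 1)).any() or not np.isfinite(r).all():
        raise ValueError("ratios must lie in [0, 1]")
    g = np.floor(r * 10).astype(int) + 1
    return np.minimum(g, 10)
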