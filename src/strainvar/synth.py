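"""Synthetic data with known ground truth for the five-population design.

The generator emulates a panel of three parental strains (LE, HW, SD) and two
cross-derived lines (LnA, LnC), each with four biological replicates, on the
log2-intensity scale.  Ground truth records per-gene strain means, the
within-strain noise level, any planted receptor-genotype (AHR) effect, and
the heritability class of each gene so that downstream estimators can be
scored against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from strainvar.core_io import PWM, ExpressionMatrix, SampleMeta

__all__ = [
    "StrainSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_expression",
    "simulate_promoters",
    "simulate_annotations",
    "simulate_homolog_map",
    "simulate_loci",
]


@dataclass(frozen=True)
class StrainSpec:
    name: str
    ancestry: dict[str, float]
    ahr_variant: int = 0


def default_strains() -> list[StrainSpec]:
    """Three parental strains plus two LE x HW cross lines; HW and LnA carry
    the variant receptor allele."""
    return [
        StrainSpec("LE", {"LE": 1.0}, 0),
        StrainSpec("HW", {"HW": 1.0}, 1),
        StrainSpec("SD", {"SD": 1.0}, 0),
        StrainSpec("LnA", {"LE": 0.5, "HW": 0.5}, 1),
        StrainSpec("LnC", {"LE": 0.5, "HW": 0.5}, 0),
    ]


# Distribution specs are ("constant", v) | ("uniform", lo, hi) |
# ("normal", sd) | ("invchisq", s0sq, d0); effect distributions get a random
# sign per draw unless the family is "normal" (already signed).
Dist = tuple


def _draw(dist: Dist, n: int, rng: np.random.Generator, signed: bool = False) -> np.ndarray:
    kind = dist[0]
    if kind == "constant":
        out = np.full(n, float(dist[1]))
    elif kind == "uniform":
        out = rng.uniform(dist[1], dist[2], size=n)
    elif kind == "normal":
        return rng.normal(0.0, dist[1], size=n)
    elif kind == "invchisq":
        s0sq, d0 = float(dist[1]), float(dist[2])
        out = s0sq * d0 / rng.chisquare(d0, size=n)
    elif kind == "beta":
        out = rng.beta(dist[1], dist[2], size=n)
    else:
        raise ValueError(f"unknown distribution family {kind!r}")
    if signed:
        out = out * rng.choice([-1.0, 1.0], size=n)
    return out


@dataclass
class SimulationConfig:
    """Parameters of the synthetic five-population world.

    Defaults emulate the real study design: 5 populations x 4 animals,
    log2 intensities spanning four expression bins (<4 unexpressed, 4-8 low,
    8-12 medium, >12 high), ~10% of genes strain-differential with effects of
    1.5-3 log2 units, a small receptor-genotype (AHR) effect set shared by HW
    and LnA, and cross-line means predominantly intermediate between the
    parents with a small planted interacting fraction.
    """

    n_genes: int = 5000
    replicates_per_strain: int = 4
    strains: list[StrainSpec] = field(default_factory=default_strains)
    fraction_strain_de: float = 0.10
    strain_effect: Dist = ("uniform", 1.5, 3.0)
    fraction_ahr_de: float = 0.005
    ahr_effect: Dist = ("uniform", 1.5, 3.0)
    fraction_interacting: float = 0.0025
    interacting_offset_factor: float = 1.5
    # per-gene parental mixing weight of the cross lines; the central peak
    # mirrors predominantly additive inheritance (use ("uniform", 0, 1) for
    # an agnostic prior)
    mixing_weight: Dist = ("beta", 2.0, 2.0)
    within_sd: Dist = ("uniform", 0.1, 0.3)
    # component weights for baseline bins <4, 4-8, 8-12, >12
    bin_weights: tuple = (0.45, 0.30, 0.20, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.fraction_strain_de, self.fraction_ahr_de, self.fraction_interacting):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.fraction_interacting > self.fraction_strain_de:
            raise ValueError("fraction_interacting cannot exceed fraction_strain_de")
        if self.fraction_strain_de + self.fraction_ahr_de > 1.0:
            raise ValueError("strain-DE and AHR-DE fractions overlap the gene universe")
        if self.replicates_per_strain < 2:
            raise ValueError("need >= 2 replicates per strain")
        if abs(sum(self.bin_weights) - 1.0) > 1e-9:
            raise ValueError("bin_weights must sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth table, one row per gene.

    Columns: one ``mean_<strain>`` per strain (full mean, receptor effect
    included), ``sigma_w``, ``ahr_effect`` (0 when not planted), ``d``
    (parental mixing weight, NaN when undefined), ``herit_class`` in
    {directional, interacting_above, interacting_below, non_de},
    ``interacting_line`` ('' | LnA | LnC | both), ``true_ratio`` = W/(W+B).
    """

    table: pd.DataFrame

    def genes_in_class(self, herit_class: str) -> list[str]:
        return list(self.table.index[self.table["herit_class"] == herit_class])

    @property
    def ahr_genes(self) -> list[str]:
        return list(self.table.index[self.table["ahr_effect"] != 0.0])


_BIN_RANGES = ((1.0, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 14.5))


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a genes x samples log2 matrix plus its ground truth.

    Per gene: a baseline intensity from the four-bin mixture; optionally a
    per-parental-strain effect (strain-DE genes); cross-line means as a convex
    combination of the LE/HW means at a shared per-gene mixing weight
    (directional; centrally peaked by default), or planted outside the
    parental range (interacting); a
    receptor-genotype effect added to every strain carrying the variant
    allele; i.i.d. Gaussian noise with per-gene sd.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    strains = config.strains
    strain_names = [s.name for s in strains]
    # pure-ancestry populations get independent strain effects; cross lines
    # (mixed ancestry) derive their means from the parents
    parents = {s.name for s in strains if s.ancestry == {s.name: 1.0}}
    gene_ids = [f"g{i:05d}" for i in range(n)]

    comp = rng.choice(4, size=n, p=np.asarray(config.bin_weights, dtype=float))
    lo = np.array([_BIN_RANGES[c][0] for c in comp])
    hi = np.array([_BIN_RANGES[c][1] for c in comp])
    baseline = rng.uniform(lo, hi)

    sigma_w = np.abs(_draw(config.within_sd, n, rng))
    if (sigma_w <= 0).any():
        raise ValueError("within-strain sd must be positive")

    # disjoint planted sets: AHR genes first, then strain-DE, interacting
    # as a subset of strain-DE
    perm = rng.permutation(n)
    n_ahr = int(round(config.fraction_ahr_de * n))
    n_de = int(round(config.fraction_strain_de * n))
    n_int = int(round(config.fraction_interacting * n))
    ahr_idx = perm[:n_ahr]
    de_idx = perm[n_ahr : n_ahr + n_de]
    int_idx = de_idx[:n_int]

    means = {name: baseline.copy() for name in strain_names}
    de_mask = np.zeros(n, dtype=bool)
    de_mask[de_idx] = True
    for name in strain_names:
        if name in parents:
            eff = np.zeros(n)
            eff[de_idx] = _draw(config.strain_effect, len(de_idx), rng, signed=True)
            means[name] = baseline + eff

    d = np.full(n, np.nan)
    herit = np.array(["non_de"] * n, dtype=object)
    int_line = np.array([""] * n, dtype=object)
    has_cross = {"LnA", "LnC"} <= set(strain_names)
    if has_cross:
        mu_le, mu_hw = means["LE"], means["HW"]
        lo_p, hi_p = np.minimum(mu_le, mu_hw), np.maximum(mu_le, mu_hw)
        span = hi_p - lo_p
        d = _draw(config.mixing_weight, n, rng)
        cross = lo_p + d * span  # shared mixing weight for both lines
        means["LnA"] = cross.copy()
        means["LnC"] = cross.copy()
        herit[de_mask] = "directional"
        for i in int_idx:
            if span[i] <= 0:
                continue
            line = rng.choice(["LnA", "LnC", "both"], p=[0.4, 0.4, 0.2])
            above = rng.random() < 0.5
            off = config.interacting_offset_factor * span[i]
            val = hi_p[i] + off if above else lo_p[i] - off
            for ln in (["LnA", "LnC"] if line == "both" else [line]):
                means[ln][i] = val
            herit[i] = "interacting_above" if above else "interacting_below"
            int_line[i] = line

    delta = np.zeros(n)
    delta[ahr_idx] = _draw(config.ahr_effect, len(ahr_idx), rng, signed=True)
    for spec in strains:
        if spec.ahr_variant:
            means[spec.name] = means[spec.name] + delta
    herit[(delta != 0) & ~de_mask] = "directional"  # AHR genes sit at d=1 w.r.t. parents

    reps = config.replicates_per_strain
    samples: list[SampleMeta] = []
    cols: dict[str, np.ndarray] = {}
    for spec in strains:
        for r in range(1, reps + 1):
            sid = f"{spec.name}_{r}"
            samples.append(SampleMeta(sid, spec.name, dict(spec.ancestry), spec.ahr_variant))
            cols[sid] = means[spec.name] + rng.normal(0.0, sigma_w)
    values = pd.DataFrame(cols, index=gene_ids)

    mean_mat = np.column_stack([means[s] for s in strain_names])
    between = mean_mat.var(axis=1, ddof=1)
    truth = pd.DataFrame(
        {
            **{f"mean_{s}": means[s] for s in strain_names},
            "sigma_w": sigma_w,
            "ahr_effect": delta,
            "d": d,
            "herit_class": herit,
            "interacting_line": int_line,
            "true_ratio": sigma_w**2 / (sigma_w**2 + between),
        },
        index=gene_ids,
    )
    return ExpressionMatrix(values, samples), SyntheticTruth(truth)


# ---------------------------------------------------------------------------
# sequence / annotation / homolog fixtures

_BASES = np.array(list("ACGT"))


def simulate_promoters(
    gene_ids,
    length: int,
    motif: PWM,
    planted_fraction: float,
    background_composition=(0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> tuple[dict[str, str], set]:
    """I.i.d. background sequences with one PWM-sampled motif instance
    planted at a uniform position/strand in a random subset of genes."""
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must lie in [0, 1]")
    if motif.length > length:
        raise ValueError("motif longer than sequence")
    rng = np.random.default_rng(seed)
    bg = np.asarray(background_composition, dtype=float)
    bg = bg / bg.sum()
    gene_ids = list(gene_ids)
    n_plant = int(round(planted_fraction * len(gene_ids)))
    planted = set(rng.choice(gene_ids, size=n_plant, replace=False)) if n_plant else set()
    freqs = motif.counts / motif.counts.sum(axis=0, keepdims=True)
    out: dict[str, str] = {}
    for gid in gene_ids:
        seq = rng.choice(4, size=length, p=bg)
        if gid in planted:
            inst = np.array([rng.choice(4, p=freqs[:, j]) for j in range(motif.length)])
            if rng.random() < 0.5:
                inst = 3 - inst[::-1]  # reverse complement in 0123 coding
            pos = rng.integers(0, length - motif.length + 1)
            seq[pos : pos + motif.length] = inst
        out[gid] = "".join(_BASES[seq])
    return out, planted


def simulate_annotations(
    gene_ids,
    n_terms: int,
    genes_per_term: int,
    coupled_set=(),
    coupled_term: str | None = None,
    enrichment_factor: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene->term table; one optional term whose membership is biased
    toward ``coupled_set`` by the given odds factor."""
    gene_ids = list(gene_ids)
    coupled_set = set(coupled_set)
    if genes_per_term > len(gene_ids):
        raise ValueError("genes_per_term exceeds number of genes")
    if not coupled_set <= set(gene_ids):
        raise ValueError("coupled_set must be a subset of gene_ids")
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_terms):
        term = f"T{t:04d}"
        if coupled_set and coupled_term is not None and term == coupled_term:
            w = np.array([enrichment_factor if g in coupled_set else 1.0 for g in gene_ids])
            members = rng.choice(gene_ids, size=genes_per_term, replace=False, p=w / w.sum())
        else:
            members = rng.choice(gene_ids, size=genes_per_term, replace=False)
        rows.extend({"gene_id": g, "term_id": term} for g in members)
    return pd.DataFrame(rows)


def simulate_loci(
    gene_ids,
    n_chromosomes: int = 20,
    chromosome_length: int = 50_000_000,
    gene_span: int = 10_000,
    clustered_set=(),
    cluster_window: int = 5_000_000,
    seed: int = 0,
):
    """Uniform random gene loci over ``n_chromosomes``; genes in
    ``clustered_set`` are packed into a single window on chromosome 1 so
    hotspot scans have a planted positive."""
    from strainvar.core_io import GeneLocus

    rng = np.random.default_rng(seed)
    clustered = set(clustered_set)
    loci = []
    for gid in gene_ids:
        if gid in clustered:
            chrom = "chr1"
            tss = int(rng.integers(1_000_000, 1_000_000 + cluster_window - gene_span))
        else:
            chrom = f"chr{rng.integers(1, n_chromosomes + 1)}"
            tss = int(rng.integers(gene_span, chromosome_length - gene_span))
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = (tss, tss + gene_span) if strand == "+" else (tss - gene_span, tss)
        loci.append(GeneLocus(gid, chrom, start, end, strand, tss))
    return loci


def simulate_homolog_map(
    rat_genes, mouse_genes, fraction_multi_match: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """One-to-one pairing of the shorter list with extra multi-matches added
    for a fraction of pairs (several probes mapping to one homolog)."""
    if not 0.0 <= fraction_multi_match <= 1.0:
        raise ValueError("fraction_multi_match must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rat = list(rat_genes)
    mouse = list(mouse_genes)
    n = min(len(rat), len(mouse))
    rat_perm = rng.permutation(rat)
    mouse_perm = rng.permutation(mouse)
    rows = [{"gene_a": rat_perm[i], "gene_b": mouse_perm[i]} for i in range(n)]
    n_extra = int(round(fraction_multi_match * n))
    spare = list(rat_perm[n:]) if len(rat) > n else []
    for j in range(n_extra):
        extra_rat = spare[j] if j < len(spare) else rng.choice(rat_perm[:n])
        rows.append({"gene_a": extra_rat, "gene_b": mouse_perm[rng.integers(0, n)]})
    return pd.DataFrame(rows)
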