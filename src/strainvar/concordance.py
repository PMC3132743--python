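"""qPCR quantification and cross-platform / cross-tissue / cross-species
concordance.

Real-time PCR abundances use the comparative-Ct method: normalized
expression NE = 2^(-ddCt) with dCt = Ct_target - Ct_reference and ddCt
relative to a calibrator dCt.  Platform concordance correlates log2 fold
changes measured by array and PCR over matched (gene, strain-pair)
comparisons (Pearson).  Cross-species comparisons pair statistics through a
homolog map (with mean/min/max collapsing of multi-matches) and use
Spearman's rho; cross-tissue comparisons summarize log2 F-statistics per
predefined gene group with Welch t-tests against the full gene set.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "ddct",
    "welch_pairwise",
    "platform_concordance",
    "homolog_aggregate",
    "cross_species_correlation",
    "cross_tissue_compare",
]


def ddct(Ct_target, Ct_reference, calibrator_dCt) -> float:
    """Normalized expression 2^(-ddCt); monotone decreasing in Ct_target."""
    d = np.asarray(Ct_target, dtype=float) - np.asarray(Ct_reference, dtype=float)
    ne = 2.0 ** -(d - np.asarray(calibrator_dCt, dtype=float))
    return float(ne) if np.ndim(ne) == 0 else ne


def welch_pairwise(values_by_strain: dict) -> pd.DataFrame:
    """Two-tailed Welch t-tests between all strain pairs.

    ``values_by_strain`` maps strain -> sequence of per-animal measurements
    (>= 2 each).  Returns one row per unordered pair with t, the
    Welch-Satterthwaite df and the two-tailed p.
    """
    for st, vals in values_by_strain.items():
        if len(vals) < 2:
            raise ValueError(f"strain {st!r} has fewer than 2 values")
    rows = []
    for a, b in itertools.combinations(values_by_strain, 2):
        x = np.asarray(values_by_strain[a], dtype=float)
        y = np.asarray(values_by_strain[b], dtype=float)
        res = stats.ttest_ind(x, y, equal_var=False)
        rows.append({"strain_a": a, "strain_b": b, "t": float(res.statistic),
                     "df": float(res.df), "p": float(res.pvalue)})
    return pd.DataFrame(rows)


def platform_concordance(fc_array, fc_pcr) -> tuple[float, float]:
    """Pearson correlation of paired log2 fold changes (array vs PCR)."""
    x = np.asarray(fc_array, dtype=float)
    y = np.asarray(fc_pcr, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired fold changes")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant fold-change vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def homolog_aggregate(
    stat_by_gene: pd.Series, homolog_map: pd.DataFrame, mode: str = "none"
) -> pd.DataFrame:
    """Pair per-gene statistics across a homolog map.

    ``homolog_map`` has columns ``gene_a`` (genes of ``stat_by_gene``) and
    ``gene_b`` (the partner species).  ``mode`` collapses multiple gene_a
    matches per gene_b: 'none' keeps every match as its own pair, or
    'mean'/'min'/'max' aggregate the statistic.  Unmatched genes are dropped
    with a logged count.
    """
    if mode not in ("none", "mean", "min", "max"):
        raise ValueError(f"unknown mode {mode!r}")
    merged = homolog_map.merge(
        stat_by_gene.rename("stat"), left_on="gene_a", right_index=True, how="left"
    )
    n_drop = int(merged["stat"].isna().sum())
    if n_drop:
        log.info("homolog_aggregate: dropped %d matches without statistics", n_drop)
    merged = merged.dropna(subset=["stat"])
    if mode == "none":
        return merged[["gene_a", "gene_b", "stat"]].reset_index(drop=True)
    agg = merged.groupby("gene_b")["stat"].agg(mode).reset_index()
    return agg.rename(columns={"stat": f"stat_{mode}"})


def cross_species_correlation(paired: pd.DataFrame, col_a: str, col_b: str) -> tuple[float, float]:
    """Spearman's rho (tie-corrected p) between two paired statistics."""
    x = paired[col_a].to_numpy(dtype=float)
    y = paired[col_b].to_numpy(dtype=float)
    if x.size < 5:
        raise ValueError("need >= 5 pairs")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def cross_tissue_compare(f_stats: pd.Series, group_assignments: dict) -> pd.DataFrame:
    """Per-group log2-F summaries with Welch tests against all genes.

    ``f_stats`` is a per-gene F statistic (multi-probe genes should already
    be averaged); ``group_assignments`` maps group name -> gene collection
    (subsets of the universe, possibly overlapping).  Returns quartiles of
    log2 F per group plus the Welch p against the 'All' reference.
    """
    universe = f_stats.dropna()
    log_all = np.log2(universe.to_numpy(dtype=float))
    rows = [_group_row("All", log_all, None)]
    for name, genes in group_assignments.items():
        genes = [g for g in genes if g in universe.index]
        if not genes:
            raise ValueError(f"group {name!r} has no genes in the universe")
        vals = np.log2(universe.loc[genes].to_numpy(dtype=float))
        p = float(stats.ttest_ind(vals, log_all, equal_var=False).pvalue) if len(vals) > 1 else np.nan
        rows.append(_group_row(name, vals, p))
    return pd.DataFrame(rows)


def _group_row(name: str, vals: np.ndarray, p) -> dict:
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {
        "group": name,
        "n": int(vals.size),
        "q1_log2F": float(q1),
        "median_log2F": float(med),
        "q3_log2F": float(q3),
        "p_vs_all": p,
    }
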