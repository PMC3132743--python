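"""Annotation-term enrichment with permutation-based FDR control.

Terms are treated as flat gene sets (any ontology propagation happens when
the annotation table is built).  Enrichment of a gene set in a term is the
one-sided hypergeometric upper-tail probability of the observed overlap.
The permutation FDR draws random same-size gene sets to build a null count
of discoveries at each candidate p cut and keeps terms at a target FDR.
Term x contrast matrices of log10 p feed the divisive clustering module, and
the cumulative rule keeps terms whose row-sum of log10 p falls below a
cutoff (default -10).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from strainvar.linear_models import ModelFit

log = logging.getLogger(__name__)

__all__ = [
    "fisher_enrichment",
    "permutation_fdr",
    "cumulative_term_selection",
    "decile_enrichment",
    "contrast_enrichment",
]


def _term_sets(annotation: pd.DataFrame, universe: set) -> dict[str, set]:
    ann = annotation[annotation["gene_id"].isin(universe)]
    return {t: set(g) for t, g in ann.groupby("term_id")["gene_id"]}


def fisher_enrichment(gene_set, universe, annotation: pd.DataFrame) -> pd.Series:
    """One-sided (upper-tail) hypergeometric enrichment p per term.

    ``annotation`` is a two-column gene_id/term_id table; terms with no
    annotated universe gene are dropped.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not gene_set or not universe:
        raise ValueError("gene set and universe must be non-empty")
    if not gene_set <= universe:
        raise ValueError("gene set must be a subset of the universe")
    N, n = len(universe), len(gene_set)
    out = {}
    for term, members in _term_sets(annotation, universe).items():
        K = len(members)
        k = len(members & gene_set)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        out[term] = float(hypergeom.sf(k - 1, N, K, n))
    return pd.Series(out, name="p").sort_index()


def permutation_fdr(
    gene_set,
    universe,
    annotation: pd.DataFrame,
    n_perm: int = 1000,
    fdr_threshold: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Terms surviving a permutation-estimated FDR.

    Random gene sets of the observed size define, for each candidate p cut
    (the observed per-term p values), the expected number of null
    discoveries; FDR(cut) = mean null discoveries / observed discoveries.
    Terms whose p sits at a cut with FDR <= threshold are returned.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    universe = list(dict.fromkeys(universe))
    gene_set = set(gene_set)
    if len(gene_set) > len(universe):
        raise ValueError("gene set larger than universe")
    observed = fisher_enrichment(gene_set, universe, annotation)

    rng = np.random.default_rng(seed)
    uni_arr = np.array(universe, dtype=object)
    null_ps = np.empty((n_perm, len(observed)))
    for b in range(n_perm):
        rand = set(rng.choice(uni_arr, size=len(gene_set), replace=False))
        null_ps[b] = fisher_enrichment(rand, universe, annotation).to_numpy()

    cuts = np.sort(observed.to_numpy())
    rows = []
    obs_arr = observed.to_numpy()
    for cut in cuts:
        n_obs = int((obs_arr <= cut).sum())
        mean_null = float((null_ps <= cut).sum(axis=1).mean())
        fdr = min(1.0, mean_null / n_obs) if n_obs else 1.0
        rows.append((cut, n_obs, mean_null, fdr))
    fdr_at_cut = {cut: fdr for cut, _, _, fdr in rows}
    keep = observed[observed.map(lambda p: fdr_at_cut[p] <= fdr_threshold)]
    return pd.DataFrame({"p": keep, "fdr": keep.map(fdr_at_cut)}).sort_values("p")


def cumulative_term_selection(matrix: pd.DataFrame, cutoff: float = -10.0) -> pd.DataFrame:
    """Keep terms (rows of log10 p) whose row-sum is at or below the cutoff,
    i.e. an unadjusted cumulative enrichment probability of 10^cutoff."""
    return matrix[matrix.sum(axis=1) <= cutoff]


def decile_enrichment(
    partition: pd.DataFrame,
    annotation: pd.DataFrame,
    min_p: float = 1e-5,
) -> pd.DataFrame:
    """Per-W/T-decile enrichment matrix (log10 p, terms x deciles).

    Rows are filtered to terms reaching p < ``min_p`` in at least one decile.
    ``result.attrs["set_size"]`` records each decile's gene count (unequal
    counts mean unequal power).
    """
    universe = list(partition.index)
    cols = {}
    sizes = {}
    all_terms = sorted(annotation.loc[annotation["gene_id"].isin(universe), "term_id"].unique())
    for decile in range(1, 11):
        genes = list(partition.index[partition["decile"] == decile])
        sizes[decile] = len(genes)
        if not genes:
            log.warning("decile %d is empty; reporting p = 1 for every term", decile)
            cols[decile] = pd.Series(1.0, index=all_terms)
        else:
            cols[decile] = fisher_enrichment(genes, universe, annotation).reindex(all_terms, fill_value=1.0)
    pmat = pd.DataFrame(cols)
    keep = pmat.min(axis=1) < min_p
    logp = np.log10(pmat[keep])
    logp.attrs["set_size"] = sizes
    return logp


def contrast_enrichment(
    simple_fit: ModelFit,
    ahr_fit: ModelFit | None,
    annotation: pd.DataFrame,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Enrichment matrix over the pairwise contrasts plus the AHR set.

    Each column takes the genes differentially expressed in that contrast
    (q < threshold) as the query set; log10 p per term, with per-column set
    sizes in ``result.attrs["set_size"]``.  Apply
    ``cumulative_term_selection`` and DIANA clustering downstream.
    """
    if ahr_fit is not None and "AHR" not in ahr_fit.q.columns:
        raise ValueError("ahr_fit lacks an AHR contrast")
    universe = list(simple_fit.q.index)
    all_terms = sorted(annotation.loc[annotation["gene_id"].isin(universe), "term_id"].unique())
    cols = {}
    sizes = {}

    def column(name: str, q: pd.Series) -> None:
        genes = list(q.index[q < q_threshold])
        sizes[name] = len(genes)
        if not genes:
            log.warning("contrast %s has no DE genes; reporting p = 1", name)
            cols[name] = pd.Series(1.0, index=all_terms)
        else:
            cols[name] = fisher_enrichment(genes, universe, annotation).reindex(all_terms, fill_value=1.0)

    if ahr_fit is not None:
        column("AHR", ahr_fit.q["AHR"])
    for contrast in simple_fit.q.columns:
        column(contrast, simple_fit.q[contrast])
    logp = np.log10(pd.DataFrame(cols))
    logp.attrs["set_size"] = sizes
    return logp
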