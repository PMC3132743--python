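"""Gene-wise linear models with empirical-Bayes variance moderation.

Two designs are supported.  The *simple* model codes each strain/line as its
own cell-mean indicator; all pairwise strain contrasts are then direct mean
differences (M-values, log2 scale).  The *ancestry_ahr* model codes each
animal by its parental ancestry proportions (a cross line carries 0.5/0.5 of
its parents) plus a binary receptor-genotype (AHR) column, so the AHR
coefficient estimates the expression shift attributable to the variant
allele after accounting for strain background.

Per-gene residual variances are shrunk toward an ensemble prior: hyper-
parameters (d0, s0^2) of a scaled inverse chi-square prior are estimated by
matching the first two moments of log s^2 to the prior predictive
(digamma/trigamma inversion), and the posterior variance
s~^2 = (d0 s0^2 + d s^2) / (d0 + d) replaces s^2 in t and F statistics,
which gain d0 extra degrees of freedom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from strainvar.core_io import PARENTAL_STRAINS, ExpressionMatrix, SampleMeta

__all__ = [
    "DesignMatrix",
    "GenewiseFit",
    "ModelFit",
    "build_design",
    "pairwise_contrast_matrix",
    "fit_genewise",
    "moderate",
    "adjust_fdr",
    "threshold_sensitivity",
    "ahr_effect_table",
    "m_to_fold_change",
]


@dataclass
class DesignMatrix:
    matrix: pd.DataFrame  # samples x coefficients
    model_kind: str  # "simple" | "ancestry_ahr"

    @property
    def coefficients(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix.to_numpy()))


def build_design(samples: list[SampleMeta], model_kind: str) -> DesignMatrix:
    """Build the simple (cell-means) or ancestry+AHR design.

    Raises on rank deficiency — the ancestry_ahr model is identifiable only
    when the populations present separate the AHR column from the strain
    background (as in the 5-population layout).
    """
    ids = [s.sample_id for s in samples]
    if model_kind == "simple":
        strains: list[str] = []
        for s in samples:
            if s.strain not in strains:
                strains.append(s.strain)
        mat = pd.DataFrame(0.0, index=ids, columns=strains)
        for s in samples:
            mat.loc[s.sample_id, s.strain] = 1.0
    elif model_kind == "ancestry_ahr":
        parents = [p for p in PARENTAL_STRAINS if any(p in s.ancestry for s in samples)]
        unknown = {p for s in samples for p in s.ancestry} - set(parents)
        if unknown:
            raise ValueError(f"ancestry references unconfigured parental strains: {sorted(unknown)}")
        mat = pd.DataFrame(0.0, index=ids, columns=list(parents) + ["AHR"])
        for s in samples:
            for p, frac in s.ancestry.items():
                mat.loc[s.sample_id, p] = frac
            mat.loc[s.sample_id, "AHR"] = float(s.ahr_variant)
    else:
        raise ValueError(f"unknown model_kind {model_kind!r}")
    if np.linalg.matrix_rank(mat.to_numpy()) < mat.shape[1]:
        raise ValueError(
            f"{model_kind} design is rank-deficient for the populations present "
            f"(columns {list(mat.columns)})"
        )
    return DesignMatrix(mat, model_kind)


def pairwise_contrast_matrix(strains) -> pd.DataFrame:
    """One +1/-1 contrast column per unordered strain pair (k*(k-1)/2)."""
    strains = list(strains)
    if len(strains) < 2:
        raise ValueError("need >= 2 strains")
    cols = {}
    for a, b in itertools.combinations(strains, 2):
        c = pd.Series(0.0, index=strains)
        c[a], c[b] = 1.0, -1.0
        cols[f"{a}_vs_{b}"] = c
    return pd.DataFrame(cols)


@dataclass
class GenewiseFit:
    """Ordinary least-squares fits, one row per gene."""

    design: DesignMatrix
    beta: pd.DataFrame  # genes x coefficients
    sigma2: pd.Series  # residual variance s^2_g
    df_resid: int
    amean: pd.Series  # average log2 intensity A
    xtx_inv: np.ndarray = field(repr=False)


def fit_genewise(X: ExpressionMatrix, D: DesignMatrix) -> GenewiseFit:
    """OLS fit of every gene against the design (shared (X'X)^-1)."""
    mat = D.matrix
    if list(mat.index) != list(X.values.columns):
        raise ValueError("samples of the expression matrix and design do not align")
    A = mat.to_numpy(dtype=float)
    Y = X.values.to_numpy(dtype=float)
    if not np.isfinite(Y).all():
        raise ValueError("non-finite expression values")
    n, p = A.shape
    df = n - int(np.linalg.matrix_rank(A))
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(A.T @ A)
    beta = Y @ A @ xtx_inv.T  # genes x p
    resid = Y - beta @ A.T
    sigma2 = (resid**2).sum(axis=1) / df
    return GenewiseFit(
        design=D,
        beta=pd.DataFrame(beta, index=X.values.index, columns=mat.columns),
        sigma2=pd.Series(sigma2, index=X.values.index, name="sigma2"),
        df_resid=df,
        amean=pd.Series(Y.mean(axis=1), index=X.values.index, name="A"),
        xtx_inv=xtx_inv,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (monotone decreasing)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs y > 0")
    return float(optimize.brentq(lambda x: special.polygamma(1, x) - y, 1e-8, 1e9, xtol=1e-12))


def estimate_prior(sigma2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled-F prior predictive of log s^2.

    Returns (inf, geometric-mean s^2) when the observed log-variance spread
    is no larger than pure sampling noise (degenerate trigamma inversion).
    """
    s2 = np.asarray(sigma2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need >= 2 positive residual variances")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = z.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(z.mean()))
    d0 = 2.0 * _trigamma_inverse(float(evar))
    s02 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


@dataclass
class ModelFit:
    """Moderated fit: shrunken variances plus per-contrast M/t/p/q and the
    overall moderated F across the contrast set."""

    design: DesignMatrix
    beta: pd.DataFrame
    sigma2: pd.Series
    df_resid: int
    amean: pd.Series
    d0: float
    s02: float
    s2_post: pd.Series
    contrasts: pd.DataFrame  # coefficients x contrast columns
    M: pd.DataFrame  # genes x contrasts
    t: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    F: pd.Series
    F_p: pd.Series
    F_q: pd.Series

    @property
    def df_total(self) -> float:
        return self.df_resid + self.d0


def moderate(
    fit: GenewiseFit,
    contrasts: pd.DataFrame | None = None,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> ModelFit:
    """Empirical-Bayes moderation of a gene-wise OLS fit.

    ``contrasts`` defaults to all pairwise strain contrasts for the simple
    model, or the single AHR coefficient for the ancestry_ahr model.
    ``prior_df``/``prior_var`` override the estimated hyperparameters
    (``prior_df=0`` reproduces ordinary t-statistics).
    """
    if contrasts is None:
        if fit.design.model_kind == "simple":
            contrasts = pairwise_contrast_matrix(fit.design.coefficients)
        else:
            contrasts = pd.DataFrame(
                {"AHR": pd.Series({c: float(c == "AHR") for c in fit.design.coefficients})}
            )
    contrasts = contrasts.reindex(fit.design.coefficients).fillna(0.0)

    n_genes = len(fit.sigma2)
    if prior_df is None or prior_var is None:
        if n_genes < 50:
            raise ValueError("hyperparameter estimation needs >= 50 genes")
        d0_est, s02_est = estimate_prior(fit.sigma2.to_numpy(), fit.df_resid)
    else:
        d0_est = s02_est = None
    d0 = float(prior_df) if prior_df is not None else d0_est
    s02 = float(prior_var) if prior_var is not None else s02_est

    s2 = fit.sigma2.to_numpy()
    df = fit.df_resid
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df

    C = contrasts.to_numpy(dtype=float)  # p x m
    B = fit.beta.to_numpy(dtype=float)
    M = B @ C  # genes x m
    U = C.T @ fit.xtx_inv @ C  # m x m covariance factor
    se = np.sqrt(np.maximum(np.diag(U), 0.0)[None, :] * s2_post[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, M / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    # overall moderated F over the contrast set (rank-reduced quadratic form)
    r = int(np.linalg.matrix_rank(U))
    U_pinv = np.linalg.pinv(U, hermitian=True)
    quad = np.einsum("gi,ij,gj->g", M, U_pinv, M)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(s2_post > 0, quad / (r * s2_post), np.inf)
    if np.isinf(df_total):
        F_p = stats.chi2.sf(r * F, r)
    else:
        F_p = stats.f.sf(F, r, df_total)

    idx = fit.beta.index
    cols = list(contrasts.columns)
    q = np.column_stack([adjust_fdr(p[:, j]) for j in range(p.shape[1])]) if p.size else p
    return ModelFit(
        design=fit.design,
        beta=fit.beta,
        sigma2=fit.sigma2,
        df_resid=df,
        amean=fit.amean,
        d0=d0,
        s02=s02,
        s2_post=pd.Series(s2_post, index=idx, name="s2_post"),
        contrasts=contrasts,
        M=pd.DataFrame(M, index=idx, columns=cols),
        t=pd.DataFrame(t, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        q=pd.DataFrame(q, index=idx, columns=cols),
        F=pd.Series(F, index=idx, name="F"),
        F_p=pd.Series(F_p, index=idx, name="F_p"),
        F_q=pd.Series(adjust_fdr(F_p), index=idx, name="F_q"),
    )


def adjust_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def threshold_sensitivity(
    fit: ModelFit, thresholds=None, use: str = "q"
) -> pd.DataFrame:
    """Differentially-expressed gene counts per contrast across a threshold
    grid (default 10^-1 .. 10^-7 in log steps); ``use`` selects adjusted
    (``q``) or raw (``p``) values."""
    if thresholds is None:
        thresholds = [10.0**-k for k in range(1, 8)]
    vals = {"q": fit.q, "p": fit.p}[use]
    return pd.DataFrame(
        {thr: (vals < thr).sum(axis=0) for thr in thresholds}
    ).rename_axis(index="contrast", columns="threshold")


def ahr_effect_table(fit: ModelFit, q_threshold: float = 0.05) -> pd.DataFrame:
    """Genes whose receptor-genotype coefficient passes the FDR threshold,
    sorted by q; M is the log2 shift attributable to the variant allele."""
    if "AHR" not in fit.M.columns:
        raise ValueError("fit has no AHR contrast; use the ancestry_ahr model")
    tab = pd.DataFrame(
        {
            "M": fit.M["AHR"],
            "t": fit.t["AHR"],
            "p": fit.p["AHR"],
            "q": fit.q["AHR"],
            "A": fit.amean,
        }
    ).sort_values("q")
    return tab[tab["q"] < q_threshold]


def m_to_fold_change(M: float) -> tuple[float, str]:
    """Convert a log2 difference to (fold change, direction).

    An M of -2.9 is a 7.5-fold repression; positive M is induction.
    """
    if not np.isfinite(M):
        raise ValueError("M must be finite")
    return float(2.0 ** abs(M)), ("repression" if M < 0 else "induction")
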