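"""Heritability of expression in cross-derived lines.

For every gene whose two parental strains differ, the position of a cross
line's mean expression inside the parental interval is summarized by

    d = (Y_test - Y_low) / (Y_high - Y_low)

where Y_high/Y_low are the higher/lower parental strain means.  d = 0 means
the line matches the lower parent, d = 1 the higher parent; d outside [0, 1]
places the line beyond the parental range.  Genes with both cross lines
inside the interval follow directional genetics; lines significantly outside
both parents (same contrast sign against each) are called interacting loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from strainvar.core_io import ExpressionMatrix
from strainvar.linear_models import ModelFit

__all__ = [
    "heritability_distance",
    "distance_profile",
    "find_interacting_loci",
    "DistanceProfile",
]


def heritability_distance(Y_test, Y_high, Y_low) -> float:
    """Position of a test line within the parental expression interval."""
    if Y_high == Y_low:
        raise ValueError("parental means are equal; distance undefined")
    if Y_high < Y_low:
        raise ValueError("Y_high must exceed Y_low")
    return (Y_test - Y_low) / (Y_high - Y_low)


@dataclass
class DistanceProfile:
    """Per-gene distance records plus Gaussian-KDE density curves, split by
    which parent is higher."""

    records: pd.DataFrame  # gene_id, Y_high, Y_low, direction, d_<line>...
    densities: dict  # (line, direction) -> (grid, density)
    bandwidths: dict


def distance_profile(
    X: ExpressionMatrix,
    gate: ModelFit,
    parent_a: str = "LE",
    parent_b: str = "HW",
    lines=("LnA", "LnC"),
    q_threshold: float = 0.05,
    grid: np.ndarray | None = None,
    bandwidth=None,
) -> DistanceProfile:
    """Distance records and density curves for genes where the two parents
    are significantly different (gate contrast q < threshold).

    The KDE uses Silverman's rule-of-thumb bandwidth unless ``bandwidth``
    overrides it; curves are returned per line and per direction
    (parent_a higher vs parent_b higher).
    """
    pair = f"{parent_a}_vs_{parent_b}"
    rev = f"{parent_b}_vs_{parent_a}"
    if pair in gate.q.columns:
        gate_q = gate.q[pair]
    elif rev in gate.q.columns:
        gate_q = gate.q[rev]
    else:
        raise ValueError(f"gate fit lacks the {parent_a}/{parent_b} contrast")
    passing = gate_q.index[gate_q < q_threshold]
    if len(passing) == 0:
        raise ValueError("no genes pass the parental differential-expression gate")

    means = X.strain_means().loc[passing]
    a, b = means[parent_a], means[parent_b]
    tested = a != b
    means = means[tested]
    a, b = a[tested], b[tested]
    hi = np.maximum(a, b)
    lo = np.minimum(a, b)
    direction = np.where(a > b, f"{parent_a}>{parent_b}", f"{parent_b}>{parent_a}")
    rec = pd.DataFrame({"Y_high": hi, "Y_low": lo, "direction": direction}, index=means.index)
    for line in lines:
        rec[f"d_{line}"] = (means[line] - lo) / (hi - lo)

    if grid is None:
        grid = np.linspace(-2.0, 3.0, 501)
    densities: dict = {}
    bandwidths: dict = {}
    for line in lines:
        for dirn in np.unique(direction):
            d = rec.loc[rec["direction"] == dirn, f"d_{line}"].to_numpy()
            if d.size < 3 or np.ptp(d) == 0:
                continue
            kde = gaussian_kde(d, bw_method="silverman" if bandwidth is None else bandwidth)
            densities[(line, dirn)] = (grid, kde(grid))
            bandwidths[(line, dirn)] = float(kde.factor * d.std(ddof=1))
    return DistanceProfile(records=rec, densities=densities, bandwidths=bandwidths)


def find_interacting_loci(
    fit: ModelFit,
    parent_a: str = "LE",
    parent_b: str = "HW",
    lines=("LnA", "LnC"),
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Gene x line records where the line differs from *both* parents in the
    same direction (both contrasts q < threshold, identical M signs).

    Requires a simple-model fit carrying line-vs-parent pairwise contrasts.
    Returns columns gene_id, line, direction (+/-), M vs each parent, q vs
    each parent, and ``in_both_lines`` flagging genes called in every line.
    """

    def line_vs(line: str, parent: str) -> tuple[pd.Series, pd.Series]:
        fwd, rev = f"{line}_vs_{parent}", f"{parent}_vs_{line}"
        if fwd in fit.M.columns:
            return fit.M[fwd], fit.q[fwd]
        if rev in fit.M.columns:
            return -fit.M[rev], fit.q[rev]
        raise ValueError(f"fit lacks contrast between {line} and {parent}")

    rows = []
    for line in lines:
        m_a, q_a = line_vs(line, parent_a)
        m_b, q_b = line_vs(line, parent_b)
        sig = (q_a < q_threshold) & (q_b < q_threshold) & (np.sign(m_a) == np.sign(m_b)) & (m_a != 0)
        for gid in fit.M.index[sig]:
            rows.append(
                {
                    "gene_id": gid,
                    "line": line,
                    "direction": "+" if m_a[gid] > 0 else "-",
                    f"M_vs_{parent_a}": m_a[gid],
                    f"M_vs_{parent_b}": m_b[gid],
                    f"q_vs_{parent_a}": q_a[gid],
                    f"q_vs_{parent_b}": q_b[gid],
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "line", "direction",
            f"M_vs_{parent_a}", f"M_vs_{parent_b}",
            f"q_vs_{parent_a}", f"q_vs_{parent_b}",
        ],
    )
    if len(out):
        counts = out.groupby("gene_id")["line"].nunique()
        out["in_both_lines"] = out["gene_id"].map(counts) == len(tuple(lines))
    else:
        out["in_both_lines"] = pd.Series(dtype=bool)
    return out
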