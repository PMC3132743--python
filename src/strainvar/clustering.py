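"""Divisive hierarchical clustering (DIANA) with correlation distance.

The pipeline clusters animals (samples) over filtered, per-gene standardized
expression profiles: genes are kept when their overall variance exceeds a
threshold (or when the overall moderated F is significant), each gene is
mean-centered and root-mean-square scaled, and the sample x sample distance
is 1 - Pearson r.  DIANA proceeds top-down: the cluster with the largest
diameter is split by seeding a splinter group with the object of maximal
average dissimilarity and migrating objects that sit closer (on average) to
the splinter than to the remainder.  Ties break toward the lowest item
index, making the tree deterministic for a given matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from strainvar.core_io import ExpressionMatrix
from strainvar.linear_models import ModelFit

__all__ = [
    "variance_filter",
    "f_statistic_filter",
    "center_scale",
    "correlation_distance",
    "correlation_distance_matrix",
    "diana",
    "cluster_agreement",
    "cluster_samples",
    "Dendrogram",
]


def variance_filter(X: ExpressionMatrix, threshold: float = 0.25) -> list[str]:
    """Genes whose variance across all samples is strictly above threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    v = X.values.var(axis=1, ddof=1)
    return list(v.index[v > threshold])


def f_statistic_filter(fit: ModelFit, p_threshold: float = 0.001) -> list[str]:
    """Genes with overall moderated-F p-value below threshold."""
    return list(fit.F_p.index[fit.F_p < p_threshold])


def center_scale(values: pd.DataFrame) -> pd.DataFrame:
    """Mean-center each row and scale it to unit root-mean-square."""
    arr = values.to_numpy(dtype=float)
    centered = arr - arr.mean(axis=1, keepdims=True)
    rms = np.sqrt((centered**2).mean(axis=1))
    if (rms == 0).any():
        bad = values.index[rms == 0][0]
        raise ValueError(f"constant gene {bad!r} cannot be scaled")
    return pd.DataFrame(centered / rms[:, None], index=values.index, columns=values.columns)


def correlation_distance(a, b) -> float:
    """1 - Pearson correlation; 0 for identical shape, 2 for anti-correlated."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant vector has undefined correlation")
    return float(1.0 - np.corrcoef(a, b)[0, 1])


def correlation_distance_matrix(values: pd.DataFrame, items: str = "columns") -> pd.DataFrame:
    """Square 1 - r distance matrix over columns (samples) or rows (genes)."""
    data = values.to_numpy(dtype=float)
    if items == "columns":
        labels = list(values.columns)
        mat = data.T
    elif items == "rows":
        labels = list(values.index)
        mat = data
    else:
        raise ValueError("items must be 'columns' or 'rows'")
    if (mat.std(axis=1) == 0).any():
        raise ValueError("constant profile has undefined correlation")
    dist = 1.0 - np.corrcoef(mat)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=labels, columns=labels)


@dataclass
class _Node:
    items: tuple
    diameter: float
    children: tuple | None = None  # (splinter, remainder)


@dataclass
class Dendrogram:
    """Binary divisive tree with per-split diameters and item labels."""

    root: _Node
    labels: list

    @property
    def n_items(self) -> int:
        return len(self.labels)

    def cut(self, k: int) -> np.ndarray:
        """Cut into k clusters by repeatedly splitting the largest-diameter
        cluster; returns integer labels aligned with ``labels``."""
        if not 1 <= k <= self.n_items:
            raise ValueError(f"k must be in 1..{self.n_items}")
        partition = [self.root]
        while len(partition) < k:
            splittable = [n for n in partition if n.children is not None]
            if not splittable:
                break
            best = max(splittable, key=lambda n: (n.diameter, -min(n.items)))
            partition.remove(best)
            partition.extend(best.children)
        out = np.empty(self.n_items, dtype=int)
        for ci, node in enumerate(partition):
            for i in node.items:
                out[i] = ci
        return out

    def split_sequence(self) -> list[tuple[tuple, tuple]]:
        """Splits in diameter order as (splinter labels, remainder labels)."""
        seq = []
        partition = [self.root]
        while any(n.children is not None for n in partition):
            best = max(
                (n for n in partition if n.children is not None),
                key=lambda n: (n.diameter, -min(n.items)),
            )
            partition.remove(best)
            partition.extend(best.children)
            seq.append(
                tuple(
                    tuple(self.labels[i] for i in sorted(child.items))
                    for child in best.children
                )
            )
        return seq

    def smallest_cluster_containing(self, labels) -> set:
        """Labels of the smallest dendrogram node containing all queried items."""
        want = {self.labels.index(l) for l in labels}
        node = self.root
        while node.children is not None:
            nxt = [c for c in node.children if want <= set(c.items)]
            if not nxt:
                break
            node = nxt[0]
        return {self.labels[i] for i in node.items}

    def to_newick(self) -> str:
        def rec(node: _Node, parent_diam: float) -> str:
            length = max(parent_diam - node.diameter, 0.0)
            if node.children is None and len(node.items) == 1:
                return f"{self.labels[node.items[0]]}:{length:.6g}"
            if node.children is None:  # unsplit zero-diameter clump
                inner = ",".join(f"{self.labels[i]}:0" for i in node.items)
                return f"({inner}):{length:.6g}"
            inner = ",".join(rec(c, node.diameter) for c in node.children)
            return f"({inner}):{length:.6g}"

        return rec(self.root, self.root.diameter) + ";"


def _diameter(d: np.ndarray, items: list) -> float:
    if len(items) < 2:
        return 0.0
    sub = d[np.ix_(items, items)]
    return float(sub.max())


def _split_cluster(d: np.ndarray, items: list) -> tuple[list, list]:
    """One DIANA split: seed the splinter with the object of maximal average
    dissimilarity, then migrate objects closer on average to the splinter."""
    items = sorted(items)
    sub = d[np.ix_(items, items)]
    m = len(items)
    avg = sub.sum(axis=1) / (m - 1)
    seed = int(np.argmax(avg))  # ties -> lowest index (argmax takes first)
    splinter = [seed]
    remainder = [i for i in range(m) if i != seed]
    while len(remainder) > 1:
        gains = []
        for i in remainder:
            a = sum(sub[i, j] for j in remainder if j != i) / (len(remainder) - 1)
            b = sum(sub[i, j] for j in splinter) / len(splinter)
            gains.append((a - b, -i))
        best_gain, neg_i = max(gains)
        if best_gain <= 0:
            break
        i = -neg_i
        remainder.remove(i)
        splinter.append(i)
    return [items[i] for i in splinter], [items[i] for i in remainder]


def diana(distance_matrix) -> Dendrogram:
    """Divisive analysis clustering of a symmetric zero-diagonal matrix."""
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        d = distance_matrix.to_numpy(dtype=float)
    else:
        d = np.asarray(distance_matrix, dtype=float)
        labels = list(range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")

    def build(items: list) -> _Node:
        diam = _diameter(d, items)
        if len(items) < 2 or diam == 0.0:
            node = _Node(tuple(sorted(items)), diam)
            if len(items) >= 2:  # zero-diameter clump still splittable for cut()
                a, b = _split_cluster(d, items)
                node.children = (build(a), build(b))
            return node
        a, b = _split_cluster(d, items)
        return _Node(tuple(sorted(items)), diam, (build(a), build(b)))

    return Dendrogram(build(list(range(d.shape[0]))), labels)


def cluster_agreement(dendrogram: Dendrogram, k: int, labels) -> float:
    """Adjusted Rand index between a k-cluster cut and reference labels."""
    labels = list(labels)
    if len(labels) != dendrogram.n_items:
        raise ValueError("label list does not match dendrogram items")
    return float(adjusted_rand_score(labels, dendrogram.cut(k)))


def cluster_samples(
    X: ExpressionMatrix,
    gene_subset=None,
    threshold: float = 0.25,
) -> Dendrogram:
    """Fig-1-style sample clustering: variance-filter genes (unless an
    explicit subset is given), center/RMS-scale each gene, DIANA on the
    1 - r sample distance matrix."""
    genes = variance_filter(X, threshold) if gene_subset is None else list(gene_subset)
    if not genes:
        raise ValueError("no genes pass the filter")
    standardized = center_scale(X.values.loc[genes])
    return diana(correlation_distance_matrix(standardized, items="columns"))
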