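"""PWM scoring of promoter sets and five-way permutation significance.

The raw motif statistic is a simplified average-likelihood-ratio score: for
one sequence, the likelihood ratio of the motif versus the background
composition is computed for every placement on both strands, and the score
is the natural log of the mean ratio (0 means no evidence; windows touching
non-ACGT characters contribute ratio 0).  A promoter set scores the mean of
its per-sequence scores.

Significance uses five separate nulls, each with its own permutation p:
(1) per-sequence mononucleotide shuffling, (2) per-sequence dinucleotide-
preserving (Euler-path) shuffling, (3) permutation of the PWM columns,
(4) random same-size promoter sets from a pool of all genes and (5) from a
pool of expressed genes.  A motif is called enriched when at least four of
the five tests fall below the p threshold on the enrichment side and the raw
score clears the score threshold; the depleted call mirrors this on the
lower tail.  Column permutation is biased against highly repetitive motifs
(a shuffled homopolymer is itself), which the multi-test rule tolerates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from strainvar.core_io import PWM, ExpressionMatrix

log = logging.getLogger(__name__)

__all__ = [
    "sequence_score",
    "set_score",
    "five_test_significance",
    "expressed_background",
    "mononucleotide_shuffle",
    "dinucleotide_shuffle",
    "TFBSResult",
]

_ENC = np.full(256, 4, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENC[ord(b)] = i
    _ENC[ord(b.lower())] = i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(enc: np.ndarray) -> str:
    return "".join("ACGTN"[i] for i in enc)


def _log_weights(pwm: PWM, background: np.ndarray, pseudocount: float) -> np.ndarray:
    """(5, L) log(freq/bg); row 4 (non-ACGT) is -inf so windows containing
    such characters score likelihood ratio 0."""
    freqs = (pwm.counts + pseudocount) / (pwm.counts.sum(axis=0) + 4 * pseudocount)
    lw = np.full((5, pwm.length), -np.inf)
    lw[:4] = np.log(freqs / background[:, None])
    return lw


def _score_encoded(lw: np.ndarray, enc: np.ndarray) -> float:
    """log mean likelihood ratio over all placements on both strands."""
    L = lw.shape[1]
    n = enc.size
    if n < L:
        raise ValueError("sequence shorter than motif")
    rc = np.where(enc == 4, 4, 3 - enc)[::-1]
    total = 0.0
    n_win = 0
    for strand in (enc, rc):
        win = np.lib.stride_tricks.sliding_window_view(strand, L)
        logs = lw[win, np.arange(L)].sum(axis=1)
        total += np.exp(logs[np.isfinite(logs)]).sum()
        n_win += win.shape[0]
    return float(np.log(total / n_win)) if total > 0 else -np.inf


def _composition(encoded_seqs) -> np.ndarray:
    counts = np.zeros(4)
    for enc in encoded_seqs:
        counts += np.bincount(enc[enc < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no ACGT content to estimate background composition")
    return counts / counts.sum()


def sequence_score(
    pwm: PWM,
    sequence: str,
    background_composition=(0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.375,
) -> float:
    """Per-sequence log-average likelihood-ratio motif score."""
    bg = np.asarray(background_composition, dtype=float)
    bg = bg / bg.sum()
    return _score_encoded(_log_weights(pwm, bg, pseudocount), _encode(sequence))


def set_score(
    pwm: PWM,
    sequences,
    background_composition=(0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.375,
) -> float:
    """Mean per-sequence score over a promoter set."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("empty sequence set")
    bg = np.asarray(background_composition, dtype=float)
    bg = bg / bg.sum()
    lw = _log_weights(pwm, bg, pseudocount)
    return float(np.mean([_score_encoded(lw, _encode(s)) for s in seqs]))


# ---------------------------------------------------------------------------
# shuffles


def mononucleotide_shuffle(enc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of the bases (exact composition preserved)."""
    return rng.permutation(enc)


_WALK = None


def _get_walk():
    global _WALK
    if _WALK is None:
        from numba import njit

        @njit(cache=False)
        def walk(succ_flat, ptr, n, start):
            out = np.empty(n, np.int8)
            out[0] = start
            v = start
            for i in range(1, n):
                nxt = succ_flat[ptr[v]]
                ptr[v] += 1
                out[i] = nxt
                v = nxt
            return out

        _WALK = walk
    return _WALK


def dinucleotide_shuffle(enc: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Euler-path shuffle preserving the exact dinucleotide count vector
    (Altschul-Erickson): fix a random last-exit edge per vertex forming an
    arborescence into the final character, shuffle the remaining exits, and
    walk the resulting Eulerian path."""
    n = enc.size
    if n <= 2 or np.unique(enc).size == 1:
        return enc.copy()
    first, last = int(enc[0]), int(enc[-1])
    succ = [enc[1:][enc[:-1] == v] for v in range(5)]
    present = [v for v in range(5) if succ[v].size > 0]

    for _ in range(1000):
        # reserve a random last-exit edge for every vertex except the final one
        last_edge = {v: int(succ[v][rng.integers(succ[v].size)]) for v in present}
        last_edge.pop(last, None)
        ok = True
        for v in last_edge:
            seen = {v}
            u = v
            while u != last:
                u = last_edge.get(u)
                if u is None or u in seen:
                    ok = False
                    break
                seen.add(u)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - arborescence sampling virtually always succeeds
        raise RuntimeError("failed to sample an Eulerian arborescence")

    offsets = np.zeros(6, dtype=np.int64)
    chunks = []
    for v in range(5):
        edges = succ[v]
        if edges.size and v in last_edge:
            le = last_edge[v]
            idx = int(np.flatnonzero(edges == le)[0])
            rest = np.delete(edges, idx)
            arranged = np.concatenate([rng.permutation(rest), np.array([le], dtype=edges.dtype)])
        elif edges.size:
            arranged = rng.permutation(edges)
        else:
            arranged = edges
        chunks.append(arranged)
        offsets[v + 1] = offsets[v] + arranged.size
    succ_flat = np.concatenate(chunks).astype(np.int8) if chunks else np.empty(0, np.int8)
    ptr = offsets[:5].copy()
    return _get_walk()(succ_flat, ptr, n, first)


# ---------------------------------------------------------------------------
# five-test significance

TEST_NAMES = ("mono", "di", "matrix", "bg_all", "bg_expressed")


@dataclass
class TFBSResult:
    motif_id: str
    raw_score: float  # mean per-sequence score of the target set
    max_sequence_score: float  # best single-promoter score (threshold gate)
    p_enrich: dict = field(default_factory=dict)  # test name -> enrichment p
    p_deplete: dict = field(default_factory=dict)
    tests_run: tuple = TEST_NAMES
    n_enriched: int = 0
    n_depleted: int = 0
    call: str = "NS"

    @property
    def n_significant(self) -> int:
        return max(self.n_enriched, self.n_depleted)


def _perm_p(null: np.ndarray, observed: float) -> tuple[float, float]:
    n = null.size
    enrich = (1 + int((null >= observed).sum())) / (n + 1)
    deplete = (1 + int((null <= observed).sum())) / (n + 1)
    return enrich, deplete


def five_test_significance(
    pwm: PWM,
    target_sequences,
    background_pool_all,
    background_pool_expressed,
    background_composition=None,
    n_perm: int = 1000,
    pseudocount: float = 0.375,
    score_threshold: float = 5.0,
    p_threshold: float = 0.05,
    seed: int = 0,
) -> TFBSResult:
    """Run the five permutation nulls against a target promoter set.

    Pools are sequence collections (promoters of all genes / of expressed
    genes); the background composition defaults to the pooled background
    content.  Pools smaller than the target set skip their test with a
    warning; the >=4 significant rule then applies to the tests actually
    run.  p-values use the add-one estimator, so they are never exactly 0.

    The score threshold is a reporting filter in the spirit of the original
    library tool: an enriched call additionally requires the motif to attain
    a per-sequence score of at least ``score_threshold`` in some target
    promoter.  (The *set* mean is not gated: signal-free promoters push the
    log-average-likelihood statistic far below zero, so a set-level gate
    would veto genuine enrichment in mixed target sets.)
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    targets = [_encode(s) for s in target_sequences]
    pool_all = [_encode(s) for s in background_pool_all]
    pool_expr = [_encode(s) for s in background_pool_expressed]
    if not targets:
        raise ValueError("empty target set")
    if background_composition is None:
        background = _composition(pool_all if pool_all else targets)
    else:
        background = np.asarray(background_composition, dtype=float)
        background = background / background.sum()
    lw = _log_weights(pwm, background, pseudocount)
    rng = np.random.default_rng(seed)

    def score_set(encs, weights=None) -> float:
        return float(np.mean([_score_encoded(weights if weights is not None else lw, e) for e in encs]))

    target_scores = np.array([_score_encoded(lw, e) for e in targets])
    observed = float(target_scores.mean())
    best = float(target_scores.max())
    p_enrich: dict = {}
    p_deplete: dict = {}
    tests_run: list[str] = []

    for name, shuffler in (("mono", mononucleotide_shuffle), ("di", dinucleotide_shuffle)):
        null = np.array(
            [score_set([shuffler(e, rng) for e in targets]) for _ in range(n_perm)]
        )
        p_enrich[name], p_deplete[name] = _perm_p(null, observed)
        tests_run.append(name)

    L = pwm.length
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = score_set(targets, weights=lw[:, rng.permutation(L)])
    p_enrich["matrix"], p_deplete["matrix"] = _perm_p(null, observed)
    tests_run.append("matrix")

    for name, pool in (("bg_all", pool_all), ("bg_expressed", pool_expr)):
        if len(pool) < len(targets):
            log.warning("background pool %s smaller than target set; test skipped", name)
            continue
        pool_scores = np.array([_score_encoded(lw, e) for e in pool])
        idx = np.arange(len(pool))
        null = np.array(
            [pool_scores[rng.choice(idx, size=len(targets), replace=False)].mean() for _ in range(n_perm)]
        )
        p_enrich[name], p_deplete[name] = _perm_p(null, observed)
        tests_run.append(name)

    n_enriched = sum(p_enrich[t] < p_threshold for t in tests_run)
    n_depleted = sum(p_deplete[t] < p_threshold for t in tests_run)
    call = "NS"
    if n_enriched >= 4 and best >= score_threshold:
        call = "enriched"
    elif n_depleted >= 4:
        call = "depleted"
    return TFBSResult(
        motif_id=pwm.motif_id,
        raw_score=observed,
        max_sequence_score=best,
        p_enrich=p_enrich,
        p_deplete=p_deplete,
        tests_run=tuple(tests_run),
        n_enriched=n_enriched,
        n_depleted=n_depleted,
        call=call,
    )


def expressed_background(X: ExpressionMatrix, threshold: float = 4.0) -> list[str]:
    """Genes whose grand-mean log2 intensity is at or above the threshold
    (the 'expressed' promoter background)."""
    means = X.values.mean(axis=1)
    return list(means.index[means >= threshold])
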