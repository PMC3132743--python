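import numpy as np
import pytest

from strainvar import tfbs
from strainvar.core_io import PWM, reverse_complement
from strainvar.synth import simulate_promoters


def _uniform_pwm(L=4):
    return PWM("UNIF", "uniform", np.full((4, L), 10.0))


class TestSequenceScore:
    def test_uniform_pwm_scores_zero(self):
        # every likelihood ratio is exactly 1 under a uniform background
        s = tfbs.sequence_score(_uniform_pwm(), "ACGTACGTACG", pseudocount=0.0)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_consensus_scores_strongly_positive(self, sharp_motif):
        s = tfbs.sequence_score(sharp_motif, sharp_motif.consensus())
        assert s > 10

    def test_hand_enumerated_windows(self):
        """3-bp motif on an 8-bp sequence: score equals the hand-summed mean
        of likelihood ratios over the 2 x 6 windows."""
        counts = np.array(
            [[8.0, 0.0, 0.0], [0.0, 8.0, 0.0], [0.0, 0.0, 8.0], [0.0, 0.0, 0.0]]
        )  # consensus ACG
        pwm = PWM("M", "ACG", counts)
        seq = "ACGTTACG"
        pc = 0.375
        freqs = (counts + pc) / (8.0 + 4 * pc)
        bg = 0.25

        def lr(word):
            out = 1.0
            for j, b in enumerate(word):
                out *= freqs["ACGT".index(b), j] / bg
            return out

        windows = [seq[i : i + 3] for i in range(6)]
        rc = reverse_complement(seq)
        windows += [rc[i : i + 3] for i in range(6)]
        expected = np.log(sum(lr(w) for w in windows) / 12)
        got = tfbs.sequence_score(pwm, seq, pseudocount=pc)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_sequence_shorter_than_motif(self, sharp_motif):
        with pytest.raises(ValueError, match="shorter"):
            tfbs.sequence_score(sharp_motif, "ACGT")

    def test_non_acgt_windows_contribute_zero(self):
        pwm = _uniform_pwm(2)
        # with an N in the middle, windows overlapping it are dropped
        s = tfbs.sequence_score(pwm, "ACNGT", pseudocount=0.0)
        # remaining windows still have LR=1 -> mean < 1 -> score < 0
        assert s < 0


class TestSetScore:
    def test_identical_sequences(self, sharp_motif):
        seq = "ACGT" * 30
        single = tfbs.sequence_score(sharp_motif, seq)
        assert tfbs.set_score(sharp_motif, [seq, seq, seq]) == pytest.approx(single)

    def test_mean_bounds(self, sharp_motif):
        rng = np.random.default_rng(0)
        bg = "".join(rng.choice(list("ACGT"), 200))
        planted = bg[:50] + sharp_motif.consensus() + bg[50:]
        lo = tfbs.sequence_score(sharp_motif, bg)
        hi = tfbs.sequence_score(sharp_motif, planted)
        mid = tfbs.set_score(sharp_motif, [bg, planted])
        assert lo < mid < hi
        assert mid == pytest.approx((lo + hi) / 2, abs=1e-12)

    def test_strand_symmetry(self, sharp_motif):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), 120)) for _ in range(5)]
        fwd = tfbs.set_score(sharp_motif, seqs)
        rev = tfbs.set_score(sharp_motif, [reverse_complement(s) for s in seqs])
        assert fwd == pytest.approx(rev, abs=1e-10)

    def test_empty_set_rejected(self, sharp_motif):
        with pytest.raises(ValueError):
            tfbs.set_score(sharp_motif, [])


class TestShuffles:
    def test_mononucleotide_preserves_composition(self):
        rng = np.random.default_rng(2)
        enc = tfbs._encode("".join(rng.choice(list("ACGT"), 500)))
        sh = tfbs.mononucleotide_shuffle(enc, rng)
        assert np.array_equal(np.bincount(sh, minlength=4), np.bincount(enc, minlength=4))

    def test_dinucleotide_preserves_exact_counts(self):
        rng = np.random.default_rng(3)

        def dicounts(e):
            c = np.zeros((4, 4), dtype=int)
            for a, b in zip(e[:-1], e[1:]):
                c[a, b] += 1
            return c

        for trial in range(20):
            enc = tfbs._encode("".join(rng.choice(list("ACGT"), 300)))
            sh = tfbs.dinucleotide_shuffle(enc, rng)
            assert np.array_equal(dicounts(sh), dicounts(enc))
            assert sh[0] == enc[0] and sh[-1] == enc[-1]

    def test_dinucleotide_shuffles_vary(self):
        rng = np.random.default_rng(4)
        enc = tfbs._encode("ACGTACGTTTGGCACAGT" * 10)
        shuffles = {tfbs._decode(tfbs.dinucleotide_shuffle(enc, rng)) for _ in range(10)}
        assert len(shuffles) > 1


class TestFiveTests:
    def _pools(self, motif, n_targets=12, n_pool=60, length=300, frac=0.5, seed=0):
        targets, _ = simulate_promoters(
            [f"t{i}" for i in range(n_targets)], length, motif, frac, seed=seed
        )
        pool, _ = simulate_promoters(
            [f"a{i}" for i in range(n_pool)], length, motif, 0.0, seed=seed + 1
        )
        return list(targets.values()), list(pool.values())

    def test_planted_motif_enriched(self, sharp_motif):
        targets, pool = self._pools(sharp_motif, seed=5)
        res = tfbs.five_test_significance(
            sharp_motif, targets, pool, pool[:30], n_perm=150, seed=6
        )
        assert res.call == "enriched"
        assert res.n_enriched >= 4
        assert res.max_sequence_score >= 5

    def test_pvalues_respect_add_one_floor(self, sharp_motif):
        targets, pool = self._pools(sharp_motif, seed=7)
        res = tfbs.five_test_significance(
            sharp_motif, targets, pool, pool[:30], n_perm=100, seed=8
        )
        for p in list(res.p_enrich.values()) + list(res.p_deplete.values()):
            assert 1 / 101 <= p <= 1.0  # never exactly zero

    def test_small_pool_skips_background_tests(self, sharp_motif, caplog):
        targets, pool = self._pools(sharp_motif, n_targets=12, seed=9)
        with caplog.at_level("WARNING"):
            res = tfbs.five_test_significance(
                sharp_motif, targets, pool[:5], pool[:5], n_perm=100, seed=10
            )
        assert res.tests_run == ("mono", "di", "matrix")
        assert "skipped" in caplog.text

    def test_repetitive_motif_matrix_test_powerless(self):
        """Column permutation cannot distinguish a homopolymer motif from
        itself, so the matrix-randomization p stays near 1-ish while the
        shuffle nulls still fire — a documented bias of that null."""
        counts = np.full((4, 8), 1.0)
        counts[0, :] = 97.0  # AAAAAAAA
        poly_a = PWM("POLYA", "repeat", counts)
        rng = np.random.default_rng(11)
        targets = ["".join(rng.choice(list("ACGT"), 150)) + "A" * 8 for _ in range(10)]
        pool = ["".join(rng.choice(list("ACGT"), 158)) for _ in range(40)]
        res = tfbs.five_test_significance(poly_a, targets, pool, pool, n_perm=120, seed=12)
        assert res.p_enrich["matrix"] > 0.5
        assert res.p_enrich["mono"] < 0.05

    def test_seed_reproducible(self, sharp_motif):
        targets, pool = self._pools(sharp_motif, seed=13)
        a = tfbs.five_test_significance(sharp_motif, targets, pool, pool[:30], n_perm=100, seed=3)
        b = tfbs.five_test_significance(sharp_motif, targets, pool, pool[:30], n_perm=100, seed=3)
        assert a.p_enrich == b.p_enrich and a.raw_score == b.raw_score


class TestExpressedBackground:
    @pytest.mark.parametrize("mean,included", [(3.999, False), (4.0, True), (9.0, True)])
    def test_threshold_boundary(self, mean, included, small_world):
        import pandas as pd

        from strainvar.core_io import ExpressionMatrix, SampleMeta

        samples = [SampleMeta(f"s{i}", "A", {"A": 1.0}) for i in range(2)]
        X = ExpressionMatrix(
            pd.DataFrame([[mean, mean]], columns=["s0", "s1"], index=["g"]), samples
        )
        assert ("g" in tfbs.expressed_background(X)) == included

    def test_bin_mixture_recovery(self, small_world):
        X, truth = small_world
        frac = len(tfbs.expressed_background(X)) / X.n_genes
        # default mixture plants 45% of baselines below 4
        assert abs(frac - 0.55) < 0.05
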