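import numpy as np
import pandas as pd
import pytest

from strainvar import linear_models as lm
from strainvar.core_io import ExpressionMatrix, SampleMeta
from strainvar.synth import SimulationConfig, simulate_expression


def _samples():
    specs = [("LE", {"LE": 1.0}, 0), ("HW", {"HW": 1.0}, 1), ("SD", {"SD": 1.0}, 0),
             ("LnA", {"LE": 0.5, "HW": 0.5}, 1), ("LnC", {"LE": 0.5, "HW": 0.5}, 0)]
    return [
        SampleMeta(f"{name}_{r}", name, dict(anc), ahr)
        for name, anc, ahr in specs
        for r in range(1, 5)
    ]


class TestBuildDesign:
    def test_simple_one_hot(self):
        D = lm.build_design(_samples(), "simple")
        mat = D.matrix
        assert mat.shape == (20, 5)
        assert D.rank == 5
        assert (mat.sum(axis=1) == 1.0).all()
        assert mat.loc["LnA_1", "LnA"] == 1.0

    def test_ancestry_row_for_cross_line(self):
        D = lm.build_design(_samples(), "ancestry_ahr")
        row = D.matrix.loc["LnA_1"]
        assert row["HW"] == 0.5 and row["LE"] == 0.5 and row["SD"] == 0.0 and row["AHR"] == 1.0

    def test_ancestry_row_for_variant_parent(self):
        D = lm.build_design(_samples(), "ancestry_ahr")
        row = D.matrix.loc["HW_1"]
        assert row["HW"] == 1.0 and row["LE"] == 0.0 and row["SD"] == 0.0 and row["AHR"] == 1.0

    def test_confounded_design_rejected(self):
        # only LE and HW present: AHR column equals the HW column
        samples = [s for s in _samples() if s.strain in ("LE", "HW")]
        with pytest.raises(ValueError, match="rank"):
            lm.build_design(samples, "ancestry_ahr")


class TestContrasts:
    @pytest.mark.parametrize("k,expected", [(2, 1), (4, 6), (5, 10)])
    def test_pair_counts(self, k, expected):
        C = lm.pairwise_contrast_matrix([f"S{i}" for i in range(k)])
        assert C.shape == (k, expected)
        assert (C.sum(axis=0) == 0).all()


class TestFitGenewise:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        samples = _samples()
        Y = rng.normal(size=(30, 20))
        X = ExpressionMatrix(
            pd.DataFrame(Y, columns=[s.sample_id for s in samples],
                         index=[f"g{i}" for i in range(30)]),
            samples,
        )
        D = lm.build_design(samples, "simple")
        fit = lm.fit_genewise(X, D)
        A = D.matrix.to_numpy()
        for i in range(30):
            beta = np.linalg.inv(A.T @ A) @ A.T @ Y[i]
            assert np.allclose(fit.beta.iloc[i].to_numpy(), beta, atol=1e-10)

    def test_two_group_difference_is_mean_difference(self):
        samples = [SampleMeta(f"A{r}", "A", {"A": 1.0}) for r in range(3)] + [
            SampleMeta(f"B{r}", "B", {"B": 1.0}) for r in range(3)
        ]
        y = np.array([[1.0, 2.0, 3.0, 7.0, 8.0, 9.0]])
        X = ExpressionMatrix(pd.DataFrame(y, columns=[s.sample_id for s in samples], index=["g"]),
                             samples)
        fit = lm.fit_genewise(X, lm.build_design(samples, "simple"))
        assert fit.beta.loc["g", "A"] - fit.beta.loc["g", "B"] == pytest.approx(-6.0, abs=1e-12)

    def test_design_column_gene_has_zero_residual(self):
        samples = _samples()
        D = lm.build_design(samples, "simple")
        y = D.matrix["HW"].to_numpy()[None, :]
        X = ExpressionMatrix(pd.DataFrame(y, columns=[s.sample_id for s in samples], index=["g"]),
                             samples)
        fit = lm.fit_genewise(X, D)
        assert fit.sigma2.loc["g"] == pytest.approx(0.0, abs=1e-20)


class TestModerate:
    def test_zero_prior_df_reproduces_ordinary_t(self, small_world):
        X, _ = small_world
        raw = lm.fit_genewise(X, lm.build_design(X.samples, "simple"))
        mod = lm.moderate(raw, prior_df=0.0, prior_var=1.0)
        C = mod.contrasts.to_numpy()
        u = np.diag(C.T @ raw.xtx_inv @ C)
        t_ord = mod.M.to_numpy() / np.sqrt(u[None, :] * raw.sigma2.to_numpy()[:, None])
        ok = raw.sigma2.to_numpy() > 0
        assert np.allclose(mod.t.to_numpy()[ok], t_ord[ok], atol=1e-8)

    def test_identical_variances_use_common_value(self):
        samples = _samples()
        rng = np.random.default_rng(0)
        # all genes share one design-fit residual pattern -> identical s2
        base = rng.normal(size=20)
        Y = np.tile(base, (60, 1)) + rng.normal(size=(60, 1))  # per-gene offset only
        X = ExpressionMatrix(pd.DataFrame(Y, columns=[s.sample_id for s in samples],
                                          index=[f"g{i}" for i in range(60)]), samples)
        raw = lm.fit_genewise(X, lm.build_design(samples, "simple"))
        assert np.allclose(raw.sigma2, raw.sigma2.iloc[0])
        mod = lm.moderate(raw)
        assert np.isinf(mod.d0)
        assert np.allclose(mod.s2_post, raw.sigma2.iloc[0], rtol=1e-9)

    def test_hyperparameter_recovery(self):
        rng = np.random.default_rng(11)
        d0, s02, df = 4.0, 0.25, 15
        sigma2_true = s02 * d0 / rng.chisquare(d0, 10000)
        s2 = sigma2_true * rng.chisquare(df, 10000) / df
        d0_hat, s02_hat = lm.estimate_prior(s2, df)
        assert 3.0 <= d0_hat <= 5.0
        assert 0.2 <= s02_hat <= 0.3

    def test_shrinkage_direction_genewise(self, simple_fit):
        """Moderation pulls t toward zero exactly for genes with s2 below the
        prior and away for genes above it."""
        s2 = simple_fit.sigma2.to_numpy()
        s2p = simple_fit.s2_post.to_numpy()
        s02 = simple_fit.s02
        below = s2 < s02
        # posterior variance lies strictly between s2 and the prior
        assert (s2p[below] > s2[below]).all() and (s2p[below] < s02).all()
        assert (s2p[~below] < s2[~below] + 1e-15).all() and (s2p[~below] >= s02).all()

    def test_pairwise_antisymmetry(self, simple_fit):
        rev = lm.pairwise_contrast_matrix(simple_fit.design.coefficients) * -1
        rev.columns = [c for c in simple_fit.M.columns]
        raw = lm.GenewiseFit(simple_fit.design, simple_fit.beta, simple_fit.sigma2,
                             simple_fit.df_resid, simple_fit.amean,
                             xtx_inv=np.linalg.inv(
                                 simple_fit.design.matrix.to_numpy().T
                                 @ simple_fit.design.matrix.to_numpy()))
        flipped = lm.moderate(raw, contrasts=rev)
        assert np.allclose(flipped.M.to_numpy(), -simple_fit.M.to_numpy(), atol=1e-12)
        assert np.allclose(flipped.p.to_numpy(), simple_fit.p.to_numpy(), atol=1e-12)


class TestFdr:
    def test_hand_step_up(self):
        q = lm.adjust_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert lm.adjust_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert (lm.adjust_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        q = lm.adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestThresholdSensitivity:
    def test_extremes(self, simple_fit):
        n = len(simple_fit.q)
        counts = lm.threshold_sensitivity(simple_fit, thresholds=[1.0001, 0.0])
        assert (counts[1.0001] == n).all()
        assert (counts[0.0] == 0).all()

    def test_counts_plateau_at_planted_truth(self):
        cfg = SimulationConfig(n_genes=2000, fraction_strain_de=0.05,
                               strain_effect=("uniform", 4.0, 5.0),
                               fraction_ahr_de=0.0, fraction_interacting=0.0,
                               within_sd=("constant", 0.2), seed=21)
        X, truth = simulate_expression(cfg)
        fit = lm.moderate(lm.fit_genewise(X, lm.build_design(X.samples, "simple")))
        counts = lm.threshold_sensitivity(fit)
        # LE vs HW: planted genes where those strains differ strongly
        de = truth.table["herit_class"] != "non_de"
        gap = (truth.table["mean_LE"] - truth.table["mean_HW"]).abs() > 2
        n_true = int((de & gap).sum())
        col = counts.loc["LE_vs_HW"]
        assert abs(col[1e-4] - n_true) <= 0.1 * n_true
        assert abs(col[1e-7] - n_true) <= 0.15 * n_true


class TestAhrEffects:
    def test_planted_sensitivity(self):
        cfg = SimulationConfig(n_genes=2000, fraction_strain_de=0.0,
                               fraction_interacting=0.0, fraction_ahr_de=0.05,
                               ahr_effect=("constant", 3.0), within_sd=("constant", 0.5),
                               seed=13)
        X, truth = simulate_expression(cfg)
        fit = lm.moderate(lm.fit_genewise(X, lm.build_design(X.samples, "ancestry_ahr")))
        tab = lm.ahr_effect_table(fit, q_threshold=0.05)
        planted = set(truth.ahr_genes)
        sens = len(planted & set(tab.index)) / len(planted)
        assert sens >= 0.9
        # M estimates the planted shift
        hits = tab.loc[tab.index.isin(planted), "M"]
        signs = np.sign(truth.table.loc[hits.index, "ahr_effect"])
        assert np.abs((hits * signs).mean() - 3.0) < 0.3

    def test_requires_ahr_model(self, simple_fit):
        with pytest.raises(ValueError, match="AHR"):
            lm.ahr_effect_table(simple_fit)


class TestFoldChange:
    @pytest.mark.parametrize(
        "M,fold,direction",
        [(-2.9, 7.5, "repression"), (0.0, 1.0, "induction"), (5.8, 55.7, "induction")],
    )
    def test_examples(self, M, fold, direction):
        f, d = lm.m_to_fold_change(M)
        assert round(f, 1) == fold
        assert d == direction
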