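import numpy as np
import pytest
from scipy import stats

from tempobias import inference
from tempobias.errors import InvalidArgumentError, SingularCovarianceError


class TestHotellingOneSample:
    def test_zero_at_mu0(self, rng):
        X = rng.normal(0, 1, (20, 3))
        res = inference.hotelling_one_sample(X, X.mean(axis=0))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_univariate_reduction(self, rng):
        x = rng.normal(0.3, 1, 25)
        res = inference.hotelling_one_sample(x[:, None], 0.0)
        t = stats.ttest_1samp(x, 0.0)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-12)
        assert res.p == pytest.approx(t.pvalue, rel=1e-12)

    def test_df_conventions(self, rng):
        # printed df pairs: (2, 191) and (5, 188) at n = 193; (2, 75) at 77;
        # (2, 74) at 76
        for n, p in [(193, 2), (193, 5), (77, 2), (76, 2)]:
            X = rng.normal(0, 1, (n, p))
            res = inference.hotelling_one_sample(X)
            assert (res.df1, res.df2) == (p, n - p)

    def test_effect_size_convention(self, rng):
        X = rng.normal(0.5, 1, (30, 2))
        res = inference.hotelling_one_sample(X)
        assert res.effect_size == pytest.approx(
            res.statistic / (res.statistic + 29), rel=1e-12
        )

    def test_singular_covariance(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10)
        X = np.column_stack([X[:, 1], X[:, 1]])
        with pytest.raises(SingularCovarianceError):
            inference.hotelling_one_sample(X)

    def test_n_le_p(self, rng):
        with pytest.raises(InvalidArgumentError):
            inference.hotelling_one_sample(rng.normal(0, 1, (3, 3)))

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(2024)
        n, p, reps = 30, 5, 2000
        rej = 0
        for _ in range(reps):
            X = rng.normal(0, 1, (n, p))
            rej += inference.hotelling_one_sample(X).p < 0.05
        assert 0.04 <= rej / reps <= 0.06


class TestHotellingTwoSample:
    def test_identical_groups(self, rng):
        X = rng.normal(0, 1, (15, 3))
        res = inference.hotelling_two_sample(X, X.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_univariate_reduction(self, rng):
        x1 = rng.normal(0, 1, 20)
        x2 = rng.normal(0.8, 1, 25)
        res = inference.hotelling_two_sample(x1[:, None], x2[:, None])
        t = stats.ttest_ind(x1, x2)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-12)
        assert res.p == pytest.approx(t.pvalue, rel=1e-12)

    def test_printed_df(self, rng):
        # p = 2 with n1 + n2 = 184 -> F(2, 181)
        X1 = rng.normal(0, 1, (92, 2))
        X2 = rng.normal(0, 1, (92, 2))
        res = inference.hotelling_two_sample(X1, X2)
        assert (res.df1, res.df2) == (2, 181)


class TestHotellingPaired:
    def test_identical_conditions(self, rng):
        X = rng.normal(0, 1, (12, 3))
        res = inference.hotelling_paired(X, X.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_reduction_identity(self, rng):
        X1 = rng.normal(0, 1, (20, 3))
        X2 = rng.normal(0.2, 1, (20, 3))
        paired = inference.hotelling_paired(X1, X2)
        onesample = inference.hotelling_one_sample(X1 - X2, 0.0)
        assert paired.statistic == pytest.approx(onesample.statistic, rel=1e-12)
        assert paired.p == pytest.approx(onesample.p, rel=1e-12)

    def test_df(self, rng):
        # n = 77, p = 3 -> standard one-sample reduction df2 = 74
        X1 = rng.normal(0, 1, (77, 3))
        X2 = rng.normal(0, 1, (77, 3))
        res = inference.hotelling_paired(X1, X2)
        assert (res.df1, res.df2) == (3, 74)


class TestRmManova:
    def test_factor_invariant_data(self, rng):
        base = rng.normal(0, 1, (15, 1, 2))
        data = np.repeat(base, 4, axis=1)
        res = inference.rm_manova(data)
        assert res.statistic == pytest.approx(1.0)
        assert res.F == pytest.approx(0.0, abs=1e-9)

    def test_paired_t_equivalence(self, rng):
        # k = 2 levels, m = 1 DV reduces to the paired t-test
        a = rng.normal(0, 1, 18)
        b = rng.normal(0.5, 1, 18)
        res = inference.rm_manova(np.stack([a, b], axis=1)[:, :, None])
        t = stats.ttest_rel(a, b)
        assert res.p == pytest.approx(t.pvalue, rel=1e-12)

    def test_lambda_in_unit_interval(self, rng):
        data = rng.normal(0, 1, (30, 5, 2))
        res = inference.rm_manova(data)
        assert 0 < res.statistic <= 1
        assert res.effect_size == pytest.approx(1 - res.statistic)

    def test_incomplete_cells(self, rng):
        data = rng.normal(0, 1, (10, 3, 2))
        data[0, 0, 0] = np.nan
        with pytest.raises(InvalidArgumentError):
            inference.rm_manova(data)

    def test_type_one_error_rate(self):
        rng = np.random.default_rng(7)
        n, k, m, reps = 40, 5, 2, 1000
        rej = 0
        for _ in range(reps):
            rej += inference.rm_manova(rng.normal(0, 1, (n, k, m))).p < 0.05
        lo, hi = stats.binom.ppf([0.025, 0.975], reps, 0.05) / reps
        assert lo <= rej / reps <= hi


class TestRmAnova:
    def test_identical_levels(self, rng):
        col = rng.normal(0, 1, 12)
        X = np.tile(col[:, None], (1, 4))
        res = inference.rm_anova(X)
        assert res.F == pytest.approx(0.0, abs=1e-9)

    def test_k2_equals_paired_t(self, rng):
        a = rng.normal(0, 1, 16)
        b = rng.normal(0.4, 1, 16)
        res = inference.rm_anova(np.stack([a, b], axis=1))
        t = stats.ttest_rel(a, b)
        assert res.epsilon_gg == pytest.approx(1.0)
        assert res.epsilon_hf == pytest.approx(1.0)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-9)
        assert res.p == pytest.approx(t.pvalue, rel=1e-9)

    def test_formula_oracle_10x3(self):
        # deletion-free recomputation of every quantity from first principles
        rng = np.random.default_rng(31)
        X = rng.normal(0, 1, (10, 3)) + rng.normal(0, 1, (10, 1))
        n, k = X.shape
        res = inference.rm_anova(X, correction="never")
        grand = X.mean()
        ss_cond = n * ((X.mean(0) - grand) ** 2).sum()
        ss_err = ((X - X.mean(0) - X.mean(1)[:, None] + grand) ** 2).sum()
        F = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        assert res.F == pytest.approx(F, abs=1e-9)
        S = np.cov(X, rowvar=False)
        C = inference.difference_contrasts(k)
        Sc = C @ S @ C.T
        eig = np.linalg.eigvalsh(Sc)
        W = np.prod(eig) / (np.mean(eig)) ** (k - 1)
        assert res.mauchly_w == pytest.approx(W, abs=1e-9)
        gg = np.trace(Sc) ** 2 / ((k - 1) * np.trace(Sc @ Sc))
        assert res.epsilon_gg == pytest.approx(gg, abs=1e-9)
        hf = min(1.0, (n * (k - 1) * gg - 2) / ((k - 1) * (n - 1 - (k - 1) * gg)))
        assert res.epsilon_hf == pytest.approx(hf, abs=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (12, 4)) + rng.normal(0, 2, (12, 1))
        res = inference.rm_anova(X, correction="never")
        df = pd.DataFrame(X, columns=list("abcd")).reset_index().melt(
            id_vars="index", var_name="cond", value_name="y"
        )
        tab = pg.rm_anova(data=df, dv="y", within="cond", subject="index",
                          correction=False)
        assert res.F == pytest.approx(tab["F"].iloc[0], rel=1e-9)
        assert res.p_uncorrected == pytest.approx(tab["p_unc"].iloc[0], rel=1e-9)
        spher = pg.sphericity(data=df, dv="y", within="cond", subject="index")
        assert res.mauchly_w == pytest.approx(spher.W, rel=1e-9)
        assert res.mauchly_p == pytest.approx(spher.pval, rel=1e-6)
        gg = pg.epsilon(data=df, dv="y", within="cond", subject="index",
                        correction="gg")
        assert res.epsilon_gg == pytest.approx(gg, rel=1e-9)

    def test_correction_policy(self, rng):
        X = rng.normal(0, 1, (20, 4))
        always = inference.rm_anova(X, correction="always")
        never = inference.rm_anova(X, correction="never")
        assert always.correction_applied
        assert not never.correction_applied
        assert always.df1_corrected == pytest.approx(
            always.epsilon_hf * always.df1
        )

    def test_k_too_small(self, rng):
        with pytest.raises(InvalidArgumentError):
            inference.rm_anova(rng.normal(0, 1, (10, 1)))


class TestHolmBonferroni:
    def test_single_p(self):
        assert inference.holm_bonferroni([0.2]) == pytest.approx([0.2])

    def test_hand_computed(self):
        adj = inference.holm_bonferroni([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_all_one(self):
        assert inference.holm_bonferroni([1.0, 1.0, 1.0]) == pytest.approx(
            [1.0, 1.0, 1.0]
        )

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.uniform(0, 1, 12)
        adj = inference.holm_bonferroni(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_order_invariance(self, rng):
        p = rng.uniform(0, 1, 9)
        perm = rng.permutation(9)
        adj = inference.holm_bonferroni(p)
        adj_perm = inference.holm_bonferroni(p[perm])
        assert np.allclose(adj[perm], adj_perm)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 10)
        ref = multipletests(p, method="holm")[1]
        assert np.allclose(inference.holm_bonferroni(p), ref)

    def test_out_of_range(self):
        with pytest.raises(InvalidArgumentError):
            inference.holm_bonferroni([0.5, 1.2])


class TestEffectSizes:
    def test_d_zero(self):
        assert inference.cohens_d_one_sample(0.0, 30) == 0.0

    def test_printed_d(self):
        # 6.87/sqrt(193) = 0.49451; the printed 0.494 came from the
        # unrounded t statistic, so allow half a unit in the 3rd decimal
        assert inference.cohens_d_one_sample(-6.87, 193) == pytest.approx(
            0.494, abs=6e-4
        )

    def test_printed_eta(self):
        assert round(inference.partial_eta_squared(10.51, 5, 188), 3) == 0.218

    def test_more_printed_pairs(self):
        # F(2, 191) = 3.50 <-> eta_p^2 = .035; t(192) = 2.62 <-> d = 0.189
        assert round(inference.partial_eta_squared(3.50, 2, 191), 3) == 0.035
        assert round(inference.cohens_d_one_sample(2.62, 193), 3) == 0.189


class TestBoxM:
    def test_identical_groups(self, rng):
        X = rng.normal(0, 1, (20, 3))
        M, chi2, df, p = inference.box_m(X, X.copy())
        assert M == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_df(self, rng):
        _, _, df, _ = inference.box_m(
            rng.normal(0, 1, (15, 3)), rng.normal(0, 1, (18, 3))
        )
        assert df == 6.0

    def test_univariate_direction(self, rng):
        # with p = 1 a large variance ratio must drive a small p-value
        a = rng.normal(0, 1, (40, 1))
        b = rng.normal(0, 4, (40, 1))
        _, _, _, p_diff = inference.box_m(a, b)
        _, _, _, p_same = inference.box_m(a, rng.normal(0, 1, (40, 1)))
        assert p_diff < 0.01 < p_same

    def test_null_rate(self):
        rng = np.random.default_rng(55)
        reps, rej = 1000, 0
        for _ in range(reps):
            a = rng.normal(0, 1, (30, 2))
            b = rng.normal(0, 1, (30, 2))
            rej += inference.box_m(a, b)[3] < 0.05
        lo, hi = stats.binom.ppf([0.025, 0.975], reps, 0.05) / reps
        assert lo <= rej / reps <= hi

    def test_singular(self):
        X = np.zeros((10, 2))
        with pytest.raises(SingularCovarianceError):
            inference.box_m(X, X)


class TestPosthoc:
    def test_table_structure(self, rng):
        X = rng.normal(0.5, 1, (25, 3))
        tab = inference.posthoc_one_sample(X, 0.0, labels=["lin", "quad", "cub"])
        assert list(tab["label"]) == ["lin", "quad", "cub"]
        assert np.all(tab["p_holm"] >= tab["p"] - 1e-15)
        ref = stats.ttest_1samp(X[:, 0], 0.0)
        assert tab["t"].iloc[0] == pytest.approx(ref.statistic, rel=1e-12)
        assert tab["p"].iloc[0] == pytest.approx(ref.pvalue, rel=1e-12)

    def test_ci_contains_mean(self, rng):
        X = rng.normal(1.0, 1, (30, 2))
        tab = inference.posthoc_one_sample(X)
        assert np.all(tab["ci_lo"] <= tab["mean"])
        assert np.all(tab["mean"] <= tab["ci_hi"])
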