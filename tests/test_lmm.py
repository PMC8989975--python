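"""Mixed-model fitting, transforms, and the fixed/random-effect tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from fusulm import DBVRecord, check_residual_normality, fit_lmm, signed_sqrt
from fusulm.lmm import test_fixed_effect as fixed_effect_f_test
from fusulm.lmm import test_random_effect as random_effect_lr_test


def balanced_one_level(n_rats=8, k=5, delta=1.0, sr=0.5, sw=1.0, seed=0):
    rng = np.random.default_rng(seed)
    y = delta + rng.normal(0, sr, n_rats)[:, None] + rng.normal(0, sw, (n_rats, k))
    return pd.DataFrame({"rat": np.repeat(np.arange(n_rats), k), "y": y.ravel()}), y


class TestSignedSqrt:
    @pytest.mark.parametrize("x,expected", [(9.0, 3.0), (0.0, 0.0), (-4.0, -2.0)])
    def test_sign_preserving_values(self, x, expected):
        assert signed_sqrt(x) == expected

    def test_literal_reading_drops_the_sign(self):
        assert signed_sqrt(-4.0, literal=True) == 2.0

    def test_odd_monotone_and_invertible(self):
        x = np.linspace(-30, 30, 301)
        y = signed_sqrt(x)
        np.testing.assert_allclose(signed_sqrt(-x), -y, atol=1e-14)
        assert np.all(np.diff(y) > 0)
        back = np.sign(y) * y**2
        np.testing.assert_allclose(back, x, rtol=1e-12, atol=1e-12)


class TestFitOneLevel:
    def test_matches_balanced_anova_closed_form(self):
        """Balanced one-way design: REML equals the textbook moment
        solution (grand mean; MSW; (MSB - MSW)/k)."""
        df, y = balanced_one_level()
        res = fit_lmm(df, "one_level")
        n_rats, k = y.shape
        gm = y.mean()
        msb = k * np.sum((y.mean(axis=1) - gm) ** 2) / (n_rats - 1)
        msw = np.sum((y - y.mean(axis=1, keepdims=True)) ** 2) / (n_rats * (k - 1))
        assert res.delta_hat == pytest.approx(gm, abs=1e-6)
        assert res.sigma2_resid == pytest.approx(msw, abs=1e-6)
        assert res.sigma2_rat == pytest.approx((msb - msw) / k, abs=1e-6)

    def test_agrees_with_statsmodels_reml(self):
        sm = pytest.importorskip("statsmodels.api")
        df, _ = balanced_one_level(seed=3)
        res = fit_lmm(df, "one_level")
        m = sm.MixedLM(df["y"], np.ones((len(df), 1)), groups=df["rat"]).fit(reml=True)
        assert res.delta_hat == pytest.approx(float(m.params.iloc[0]), abs=1e-5)
        assert res.reml_loglik >= m.llf - 1e-6  # never a worse optimum

    def test_no_rat_effect_collapses_to_sample_mean(self):
        # a realization whose between-rat mean square falls below the
        # within mean square, so the REML boundary estimate is exactly 0
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"rat": np.repeat(np.arange(10), 4),
                           "y": 2.0 + rng.normal(0, 1, 40)})
        res = fit_lmm(df, "one_level")
        assert res.sigma2_rat == pytest.approx(0.0, abs=1e-6)
        assert res.delta_hat == pytest.approx(df["y"].mean(), abs=1e-6)

    def test_translation_equivariance(self):
        df, _ = balanced_one_level(seed=5)
        a = fit_lmm(df, "one_level")
        b = fit_lmm(df.assign(y=df["y"] + 10.0), "one_level")
        assert b.delta_hat == pytest.approx(a.delta_hat + 10.0, abs=1e-8)
        assert b.sigma2_rat == pytest.approx(a.sigma2_rat, abs=1e-5)
        assert b.sigma2_resid == pytest.approx(a.sigma2_resid, abs=1e-5)

    def test_accepts_record_objects(self):
        recs = [DBVRecord(rat=i // 3, y=float(i)) for i in range(12)]
        res = fit_lmm(recs, "one_level")
        assert res.n_obs == 12 and res.n_rats == 4

    def test_single_rat_rejected(self):
        df = pd.DataFrame({"rat": [0, 0, 0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="rat"):
            fit_lmm(df, "one_level")


class TestFitTwoLevel:
    def _nested(self, n_rats=6, n_acq=3, k=4, delta=1.0, sr=0.5, sa=0.4, sw=1.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_rats):
            R = rng.normal(0, sr)
            for j in range(n_acq):
                A = rng.normal(0, sa)
                rows += [{"rat": i, "acquisition": j, "y": delta + R + A + rng.normal(0, sw)}
                         for _ in range(k)]
        return pd.DataFrame(rows)

    def test_agrees_with_statsmodels_nested_vc(self):
        sm = pytest.importorskip("statsmodels.api")
        df = self._nested(seed=2)
        res = fit_lmm(df, "two_level")
        m = sm.MixedLM.from_formula(
            "y ~ 1", groups="rat", re_formula="1",
            vc_formula={"acq": "0 + C(acquisition)"}, data=df,
        ).fit(reml=True)
        assert res.delta_hat == pytest.approx(float(m.params.iloc[0]), abs=1e-3)
        assert res.reml_loglik >= m.llf - 1e-5

    def test_single_acquisition_per_rat_reduces_to_one_level(self):
        df = self._nested(n_acq=1, seed=4)
        res = fit_lmm(df, "two_level")
        one = fit_lmm(df, "one_level")
        assert "acquisition_variance_confounded_with_rat" in res.flags
        assert res.sigma2_acq == 0.0
        assert res.delta_hat == pytest.approx(one.delta_hat, abs=1e-10)
        assert res.reml_loglik == pytest.approx(one.reml_loglik, abs=1e-10)


class TestFixedEffectTest:
    def test_one_observation_per_rat_equals_one_sample_t(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0.5, 1, 12)
        df = pd.DataFrame({"rat": np.arange(12), "y": y})
        res = fixed_effect_f_test(fit_lmm(df, "one_level"))
        t = y.mean() / (y.std(ddof=1) / np.sqrt(12))
        assert res.fstat == pytest.approx(t**2, rel=1e-10)
        assert res.f_df == (1, 11)
        assert "rat_variance_confounded_with_residual" in res.flags

    def test_strong_effect_detected(self):
        detected = 0
        for seed in range(20):
            df, _ = balanced_one_level(n_rats=12, k=5, delta=3.0, sr=1.0, sw=1.0, seed=seed)
            res = fixed_effect_f_test(fit_lmm(df, "one_level"))
            detected += res.f_p < 0.001
        assert detected >= 19

    def test_satterthwaite_df_between_rat_and_residual_df(self):
        df, _ = balanced_one_level(n_rats=10, k=5, sr=1.0, seed=8)
        res = fixed_effect_f_test(fit_lmm(df, "one_level"), ddf_method="satterthwaite")
        # with a strong rat effect the effective df approaches n_rats - 1
        assert 2 < res.f_df[1] < 50


class TestRandomEffectTest:
    def test_identical_models_give_lr_zero_p_one(self):
        df, _ = balanced_one_level(seed=9)
        full = fit_lmm(df, "one_level")
        lr, p = random_effect_lr_test(full, full)
        assert lr == 0.0 and p == 1.0

    def test_large_rat_variance_strongly_rejected(self):
        df, _ = balanced_one_level(n_rats=15, k=6, sr=3.0, sw=1.0, seed=11)
        full = fit_lmm(df, "one_level")
        reduced = fit_lmm(df, "iid")
        lr, p = random_effect_lr_test(full, reduced)
        assert p < 1e-4

    def test_null_lr_conservative_against_chi2_1(self):
        """With sigma_R = 0, the LR statistic is stochastically dominated
        by chi-squared(1): the plain reference over-covers."""
        rej = 0
        n = 200
        for seed in range(n):
            rng = np.random.default_rng(20000 + seed)
            df = pd.DataFrame({"rat": np.repeat(np.arange(10), 4),
                               "y": rng.normal(0, 1, 40)})
            full = fit_lmm(df, "one_level")
            reduced = fit_lmm(df, "iid")
            _, p = random_effect_lr_test(full, reduced)
            rej += p < 0.05
        assert rej / n <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)

    def test_boundary_mixture_halves_p(self):
        df, _ = balanced_one_level(seed=13)
        full = fit_lmm(df, "one_level")
        reduced = fit_lmm(df, "iid")
        lr, p_plain = random_effect_lr_test(full, reduced)
        if lr > 0:
            _, p_mix = random_effect_lr_test(full, reduced, boundary_mixture=True)
            assert p_mix == pytest.approx(p_plain / 2)

    def test_non_nested_pair_rejected(self):
        df, _ = balanced_one_level(seed=1)
        one = fit_lmm(df, "one_level")
        iid = fit_lmm(df, "iid")
        with pytest.raises(ValueError, match="nested"):
            random_effect_lr_test(iid, one)


class TestResidualNormality:
    def test_gaussian_residual_p_values_roughly_uniform(self):
        """Shapiro-Wilk p on normal data should look uniform across seeds
        (Kolmogorov-Smirnov sanity check)."""
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"rat": np.repeat(np.arange(10), 5),
                               "y": rng.normal(0, 1, 50) + rng.normal(0, 0.5, 10)[np.repeat(np.arange(10), 5)]})
            _, p = check_residual_normality(fit_lmm(df, "one_level"))
            ps.append(p)
        ks = scipy.stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.001

    def test_skewed_residuals_rejected(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"rat": np.repeat(np.arange(10), 5),
                               "y": np.exp(rng.normal(0, 1, 50))})
            _, p = check_residual_normality(fit_lmm(df, "one_level"))
            hits += p < 0.05
        assert hits >= 45

    def test_minimal_three_residuals_returns_finite_statistic(self):
        df = pd.DataFrame({"rat": [0, 1, 2], "y": [1.0, 2.0, 2.5]})
        stat, p = check_residual_normality(fit_lmm(df, "one_level"))
        assert np.isfinite(stat) and 0 <= p <= 1

    def test_constant_residuals_rejected(self):
        df = pd.DataFrame({"rat": [0, 0, 1, 1], "y": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            check_residual_normality(fit_lmm(df, "one_level"))
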