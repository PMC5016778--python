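"""Correlation, regression, GLM and diagnostic layer against independent
oracles: normal equations, exhaustive permutation, closed forms."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from coastnis import (
    ValidationError,
    bonferroni,
    breusch_pagan,
    durbin_watson,
    fit_glm_normal,
    fit_mlr,
    fit_ols,
    pearson,
    regression_diagnostics,
    shapiro_wilk,
)


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

class TestPearson:
    def test_survey_aquaculture_correlation(self, table1):
        res = pearson(table1.frame["aquaculture"], table1.frame["nis_prop"])
        assert res.r == pytest.approx(0.673, abs=0.01)
        assert res.df == 28
        assert res.p_value == pytest.approx(5e-5, abs=3e-5)

    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-12

    def test_symmetry_and_affine_invariance(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        a = pearson(x, y)
        assert pearson(y, x).r == pytest.approx(a.r)
        assert pearson(3.0 * x + 7.0, y).r == pytest.approx(a.r)
        assert pearson(-2.0 * x, y).r == pytest.approx(-a.r)

    def test_t_from_r_identity(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = pearson(x, y)
        assert res.t_stat == pytest.approx(
            res.r * math.sqrt(res.df / (1 - res.r**2))
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson([1, 1, 1, 1], [1, 2, 3, 4])

    def test_permutation_p_matches_exhaustive_enumeration(self, rng):
        """Monte-Carlo permutation p agrees with the exact p from full
        enumeration of all n! shuffles at n = 7."""
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        r_obs = abs(pearson(x, y).r)
        hits = total = 0
        for perm in itertools.permutations(y):
            total += 1
            if abs(np.corrcoef(x, perm)[0, 1]) >= r_obs - 1e-12:
                hits += 1
        exact = hits / total
        res = pearson(x, y, n_perm=4999, seed=11)
        mc_err = 3 * math.sqrt(exact * (1 - exact) / 4999)
        assert res.p_permutation == pytest.approx(exact, abs=mc_err + 1e-3)

    def test_t_and_permutation_p_agree_for_gaussian_data(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        res = pearson(x, y, n_perm=20000, seed=5)
        assert res.p_permutation == pytest.approx(res.p_value, abs=0.03)


class TestBonferroni:
    def test_declared_family_of_twelve(self):
        res = bonferroni([0.001], m=12)
        assert round(res.threshold, 4) == 0.0042
        assert res.significant == (True,)
        # the survey's r = -0.543 screen call: p = 0.0019 clears 0.05/12
        assert bonferroni([0.0019], m=12).significant == (True,)

    def test_single_test(self):
        assert bonferroni([0.001], m=1).significant == (True,)
        assert bonferroni([0.06], m=1).significant == (False,)

    def test_family_defaults_to_length(self):
        res = bonferroni([0.01, 0.004])
        assert res.m == 2 and res.threshold == 0.025


# ---------------------------------------------------------------------------
# multiple linear regression
# ---------------------------------------------------------------------------

class TestMlr:
    def test_coefficients_match_normal_equations_oracle(self, rng):
        n, k = 20, 3
        X = rng.normal(size=(n, k))
        y = rng.normal(size=n)
        frame = pd.DataFrame(X, columns=["a", "b", "c"])
        frame["y"] = y
        res = fit_mlr(frame, "y", ["a", "b", "c"])
        design = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        for j, name in enumerate(["a", "b", "c"]):
            assert res.coefficients[name] == pytest.approx(beta[j + 1], abs=1e-10)
        # F from the explicit ANOVA decomposition
        e = y - design @ beta
        sse = float(e @ e)
        ssr = float(((design @ beta) - y.mean()) ** 2 @ np.ones(n))
        assert res.f_stat == pytest.approx((ssr / k) / (sse / (n - k - 1)), rel=1e-10)

    def test_single_predictor_t_squared_equals_f(self, rng):
        x = rng.normal(size=15)
        y = 2 * x + rng.normal(size=15)
        res = fit_ols(x, y)
        assert res.t_values["x"] ** 2 == pytest.approx(res.f_stat, rel=1e-9)

    def test_exact_fit_reports_infinite_f(self):
        frame = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [2.0, 4, 6, 8, 10]})
        res = fit_mlr(frame, "y", ["x"])
        assert res.r2 == pytest.approx(1.0)
        assert math.isinf(res.f_stat)
        assert res.p_overall == 0.0

    def test_survey_modeling_degrees_of_freedom(self, table1_no_outliers):
        from coastnis.pipeline import DEFAULT_PREDICTORS

        res = fit_mlr(table1_no_outliers, "nis_prop", list(DEFAULT_PREDICTORS))
        assert (res.df1, res.df2) == (12, 15)
        assert res.nobs == 28

    def test_collinear_design_names_columns(self, rng):
        frame = pd.DataFrame({"a": rng.normal(size=12)})
        frame["b"] = 2 * frame["a"]
        frame["y"] = rng.normal(size=12)
        with pytest.raises(ValidationError, match="[ab]"):
            fit_mlr(frame, "y", ["a", "b"])

    def test_too_few_observations_rejected(self, rng):
        frame = pd.DataFrame(rng.normal(size=(3, 3)), columns=["a", "b", "y"])
        with pytest.raises(ValidationError, match="n > k"):
            fit_mlr(frame, "y", ["a", "b"])


# ---------------------------------------------------------------------------
# normal-family GLM
# ---------------------------------------------------------------------------

class TestGlmNormal:
    def test_identity_link_reproduces_ols(self, rng):
        x = rng.normal(size=30)
        y = 0.5 - 0.2 * x + rng.normal(scale=0.3, size=30)
        glm = fit_glm_normal(x, y, link="identity")
        ols = fit_ols(x, y)
        assert glm.slope == pytest.approx(ols.coefficients["x"], rel=1e-10)
        assert glm.intercept == pytest.approx(ols.intercept, rel=1e-10)
        # the scaled-deviance G equals the squared slope t under identity
        assert glm.g_stat == pytest.approx(ols.t_values["x"] ** 2, rel=1e-9)

    def test_dispersion_is_deviance_over_df(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        glm = fit_glm_normal(x, y)
        assert glm.phi == pytest.approx(glm.deviance / 23)

    def test_g_nonnegative_and_orders_fits_like_f(self, rng):
        """G and the OLS F rank a family of datasets identically."""
        gs, fs = [], []
        for slope in (0.0, 0.3, 0.8, 2.0):
            x = rng.normal(size=40)
            y = slope * x + rng.normal(size=40)
            gs.append(fit_glm_normal(x, y).g_stat)
            fs.append(fit_ols(x, y).f_stat)
        assert all(g >= 0 for g in gs)
        assert np.argsort(gs).tolist() == np.argsort(fs).tolist()

    def test_log_link_recovers_exponential_truth(self, rng):
        """y = exp(a + bx) + noise at n = 200: the 2-SE interval around the
        fitted (a, b) covers the truth at its nominal ~95% rate over
        replicates (a single draw is a coin flip by design)."""
        import statsmodels.api as sm

        a, b, n = 0.2, 0.7, 200
        fam = sm.families.Gaussian(link=sm.families.links.Log())
        covered = 0
        n_rep = 15
        for _ in range(n_rep):
            x = rng.uniform(0, 2, size=n)
            y = np.exp(a + b * x) + rng.normal(scale=0.2, size=n)
            glm = fit_glm_normal(x, y, link="log")
            ref = sm.GLM(y, np.column_stack([np.ones(n), x]), family=fam).fit()
            assert glm.slope == pytest.approx(ref.params[1], rel=1e-6)
            covered += (
                abs(glm.slope - b) < 2 * ref.bse[1]
                and abs(glm.intercept - a) < 2 * ref.bse[0]
            )
        assert covered >= 12  # binomial(15, ~0.9) lower tail is negligible

    def test_log_link_handles_zero_response(self, table1_no_outliers):
        """The survey response contains exact zeros; the guarded start must
        still give positive fitted means and a finite fit."""
        frame = table1_no_outliers.frame
        glm = fit_glm_normal(frame["aquaculture"], frame["nis_prop"], link="log")
        assert glm.converged
        assert glm.slope > 0  # more farming, more invaders

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError):
            fit_glm_normal([1, 1, 1, 1], [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

class TestDurbinWatson:
    def test_constant_residuals_give_zero(self):
        dw, _ = durbin_watson([1.0, 1, 1, 1], n_perm=0)
        assert dw == 0.0

    def test_alternating_residuals_approach_four(self):
        e = [(-1.0) ** t for t in range(100)]
        dw, _ = durbin_watson(e, n_perm=0)
        assert dw > 3.9

    def test_range_and_exchangeable_mean(self, rng):
        """DW stays in [0, 4] and averages ~2(n-1)/n (~2) under exchangeable
        residuals."""
        n = 30
        stats = []
        for _ in range(300):
            dw, _ = durbin_watson(rng.normal(size=n), n_perm=0)
            assert 0.0 <= dw <= 4.0
            stats.append(dw)
        assert np.mean(stats) == pytest.approx(2 * (n - 1) / n, abs=0.05)

    def test_permutation_p_detects_strong_autocorrelation(self, rng):
        e = np.cumsum(rng.normal(size=40))  # random walk: strong lag-1 memory
        dw, p = durbin_watson(e, n_perm=999, seed=2)
        assert dw < 1.0 and p < 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            durbin_watson([0.0, 0.0, 0.0])


class TestBreuschPagan:
    def test_constant_residuals_score_zero(self, rng):
        stat, p = breusch_pagan(rng.normal(size=20), np.zeros(20))
        assert stat == 0.0 and p == 1.0

    def test_matches_nr2_oracle(self, rng):
        x = rng.normal(size=50)
        y = 1 + x + rng.normal(size=50) * (1 + np.abs(x))
        res = fit_ols(x, y)
        e = np.asarray(res.residuals)
        stat, _ = breusch_pagan(x, e)
        aux = fit_ols(x, e**2)
        assert stat == pytest.approx(50 * aux.r2, rel=1e-8)

    def test_power_against_variance_proportional_to_x_squared(self, rng):
        rejections = 0
        for _ in range(50):
            x = rng.uniform(0.5, 2.0, size=200)
            y = 1 + 2 * x + rng.normal(size=200) * x**2
            e = np.asarray(fit_ols(x, y).residuals)
            _, p = breusch_pagan(x, e)
            rejections += p < 0.05
        assert rejections >= 40  # >= 80% power

    def test_bundled_diagnostics(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        e = np.asarray(fit_ols(x, y).residuals)
        diag = regression_diagnostics(x, e, n_perm=199, seed=0)
        assert 0 <= diag.durbin_watson <= 4
        assert 0 <= diag.bp_p <= 1
        assert 0 <= diag.shapiro_p <= 1

    def test_shapiro_flags_heavy_skew(self, rng):
        _, p_normal = shapiro_wilk(rng.normal(size=100))
        _, p_skew = shapiro_wilk(rng.exponential(size=100) ** 2)
        assert p_skew < 0.001 < p_normal
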