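"""Logistic MLE: closed forms, score equations, failure modes, profile CIs."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from causalrd.cohort import CohortTable, DesignMatrix, build_design, default_codebook
from causalrd.errors import (
    AlignmentError,
    DegenerateResponseError,
    SeparationError,
)
from causalrd.glm import (
    _profile_ll,
    fit_group_outcome_models,
    fit_logistic,
    predict_probability,
    profile_likelihood_ci,
)
from tests.conftest import toy_cohort


def design_from(X, labels=None):
    X = np.asarray(X, dtype=float)
    labels = labels or tuple(f"c{i}" for i in range(X.shape[1]))
    return DesignMatrix(X, tuple(labels))


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        # 178 poor-health cases out of 805: MLE intercept log(178/627)
        y = np.zeros(805)
        y[:178] = 1
        fit = fit_logistic(design_from(np.ones((805, 1))), y)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(np.log(178 / 627), abs=1e-10)

    def test_two_by_two_closed_form(self):
        # saturated 2x2: slope is the log odds ratio log(ad/bc)
        a, b, c, d = 30, 50, 20, 80  # (y=1,x=1), (y=0,x=1), (y=1,x=0), (y=0,x=0)
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_logistic(design_from(X), y)
        assert fit.beta[1] == pytest.approx(np.log(a * d / (b * c)), abs=1e-10)

    @pytest.mark.parametrize("value", [0.0, 1.0])
    def test_constant_response_degenerate(self, value):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(DegenerateResponseError):
            fit_logistic(design_from(X), np.full(20, value))

    def test_perfect_separation_detected(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        X = np.column_stack([np.ones_like(x), x])
        with pytest.raises(SeparationError) as err:
            fit_logistic(design_from(X, ("intercept", "slope")), y)
        assert err.value.column == "slope"

    def test_score_equations_hold_at_optimum(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(300), rng.standard_normal((300, 3))])
        y = (rng.random(300) < expit(X @ np.array([-0.5, 0.8, -0.3, 0.2]))).astype(float)
        fit = fit_logistic(design_from(X), y)
        score = X.T @ (y - fit.fitted)
        assert np.max(np.abs(score)) < 1e-6

    def test_frequency_weight_equivalence(self):
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(50), rng.integers(0, 2, 50).astype(float)])
        y = rng.integers(0, 2, 50).astype(float)
        reps = rng.integers(1, 4, 50)
        Xdup = np.repeat(X, reps, axis=0)
        ydup = np.repeat(y, reps)
        fit_dup = fit_logistic(design_from(Xdup), ydup)
        fit_w = fit_logistic(design_from(X), y, freq_weights=reps.astype(float))
        np.testing.assert_allclose(fit_dup.beta, fit_w.beta, atol=1e-8)

    def test_matches_statsmodels(self, cohort805):
        design = build_design(
            cohort805, ["education", "previous_health", "marital"],
            include_exposure=True,
        )
        ours = fit_logistic(design, cohort805.y)
        ref = sm.Logit(cohort805.y, design.matrix).fit(disp=0)
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-6)

    def test_warm_start_reaches_same_mle(self, cohort805):
        design = build_design(cohort805, ["education", "smoking"])
        cold = fit_logistic(design, cohort805.x)
        warm = fit_logistic(design, cohort805.x, beta0=cold.beta + 0.5)
        np.testing.assert_allclose(cold.beta, warm.beta, atol=1e-8)


class TestPredict:
    def test_zero_coefficients_give_half(self):
        d = design_from(np.ones((5, 1)))
        fit = fit_logistic(d, np.array([0, 1, 0, 1, 1.0]))
        fit.beta[:] = 0.0
        assert np.all(predict_probability(fit, d) == 0.5)

    def test_log3_gives_three_quarters(self):
        d = design_from(np.ones((4, 1)))
        fit = fit_logistic(d, np.array([0, 1, 1, 0.0]))
        fit.beta[:] = np.log(3.0)
        np.testing.assert_allclose(predict_probability(fit, d), 0.75)

    def test_column_mismatch_rejected(self):
        d = design_from(np.ones((4, 1)), ("intercept",))
        fit = fit_logistic(d, np.array([0, 1, 1, 0.0]))
        other = design_from(np.ones((4, 1)), ("shifted",))
        with pytest.raises(AlignmentError):
            predict_probability(fit, other)


class TestGroupOutcomeModels:
    def test_constant_outcome_stratum_is_singular(self, codebook):
        cohort = toy_cohort(
            y=[1] * 10 + [0, 1] * 10, x=[1] * 10 + [0] * 20
        )
        with pytest.raises(DegenerateResponseError):
            fit_group_outcome_models(cohort, [])

    def test_intercept_only_predictions_are_group_means(self):
        y = [1, 1, 0, 1, 0, 0, 1, 0, 0, 0]
        x = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        cohort = toy_cohort(y=y, x=x)
        gm = fit_group_outcome_models(cohort, [])
        np.testing.assert_allclose(gm.m1, 3 / 4, atol=1e-9)
        np.testing.assert_allclose(gm.m0, 1 / 6, atol=1e-9)

    def test_predictions_cover_all_rows(self, cohort805):
        gm = fit_group_outcome_models(cohort805, ["previous_health", "education"])
        assert gm.m0.shape == (805,) and gm.m1.shape == (805,)
        assert np.all((gm.m0 > 0) & (gm.m0 < 1))
        assert np.all((gm.m1 > 0) & (gm.m1 < 1))


class TestProfileLikelihoodCI:
    def grid_oracle(self, design, y, j, fit, level=0.95):
        """Dense grid search for the profile interval bounds."""
        q = stats.chi2.ppf(level, 1)
        se = np.sqrt(fit.covariance(design)[j, j])
        grid = np.linspace(fit.beta[j] - 6 * se, fit.beta[j] + 6 * se, 4001)
        pll = np.array([_profile_ll(design, y, j, b) for b in grid])
        inside = 2 * (fit.log_likelihood - pll) <= q
        return grid[inside][0], grid[inside][-1]

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(21)
        n = 120
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < expit(-0.3 + 0.9 * x)).astype(float)
        design = design_from(
            np.column_stack([np.ones(n), x]), ("intercept", "x")
        )
        fit = fit_logistic(design, y)
        lo, hi = profile_likelihood_ci(fit, design, y, 1)
        glo, ghi = self.grid_oracle(design, y, 1, fit)
        # grid spacing is 6*se*2/4000 ~ 6e-4 on the beta scale
        assert np.log(lo) == pytest.approx(glo, abs=2e-3)
        assert np.log(hi) == pytest.approx(ghi, abs=2e-3)

    def test_interval_contains_point_estimate(self, cohort805):
        design = build_design(cohort805, ["previous_health"], include_exposure=True)
        fit = fit_logistic(design, cohort805.y)
        j = design.column_index("exposure")
        lo, hi = profile_likelihood_ci(fit, design, cohort805.y, j)
        assert lo < np.exp(fit.beta[j]) < hi

    def test_null_effect_straddles_one_large_n(self):
        rng = np.random.default_rng(3)
        n = 100_000
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < 0.3).astype(float)
        design = design_from(np.column_stack([np.ones(n), x]))
        fit = fit_logistic(design, y)
        lo, hi = profile_likelihood_ci(fit, design, y, 1)
        assert lo < 1.0 < hi

    def test_agrees_with_wald_at_large_n(self):
        rng = np.random.default_rng(8)
        n = 100_000
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(0.2 + 0.5 * x)).astype(float)
        design = design_from(np.column_stack([np.ones(n), x]))
        fit = fit_logistic(design, y)
        lo, hi = profile_likelihood_ci(fit, design, y, 1)
        se = np.sqrt(fit.covariance(design)[1, 1])
        wlo, whi = np.exp(fit.beta[1] + np.array([-1, 1]) * 1.959964 * se)
        profile_width = np.log(hi) - np.log(lo)
        wald_width = np.log(whi) - np.log(wlo)
        assert abs(profile_width - wald_width) / wald_width < 0.02

    def test_asymmetric_with_sparse_events(self):
        # 2 events in 40: the log-likelihood is skewed, so the profile
        # interval for the intercept is asymmetric on the log-odds scale
        y = np.r_[np.ones(2), np.zeros(38)]
        design = design_from(np.ones((40, 1)), ("intercept",))
        fit = fit_logistic(design, y)
        lo, hi = profile_likelihood_ci(fit, design, y, 0)
        b = fit.beta[0]
        lower_arm = b - np.log(lo)
        upper_arm = np.log(hi) - b
        assert abs(upper_arm - lower_arm) / upper_arm > 0.05
        assert lo < np.exp(b) < hi
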