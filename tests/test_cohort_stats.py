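"""Pearson correlation and logistic regression with pseudo-R².

The IRLS fit is checked two ways that stay independent of it: against
statsmodels' Logit maximum-likelihood fit, and against a Nelder-Mead
maximisation of a log-likelihood written out directly in the test.
"""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize

from stonevol.cohort_stats import (
    fit_logistic,
    nagelkerke_r2,
    pearson_r,
    rank_predictors,
)
from stonevol.errors import DomainError, UndefinedStatisticError
from stonevol.phantom import CohortSpec, simulate_cohort

# non-separable toy data: overlapping classes along x
TOY_Y = np.array([0, 0, 1, 0, 1, 0, 1, 1, 0, 1, 1, 1], dtype=float)
TOY_X = np.arange(1.0, 13.0)


class TestPearson:
    def test_identity_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson_r(x, x).r == pytest.approx(1.0)

    def test_negative_affine_is_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert pearson_r(x, -2 * x + 7).r == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # r = 6.5 / sqrt(5 * 8.75) from the product-moment definition
        res = pearson_r(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 5]))
        assert res.r == pytest.approx(6.5 / math.sqrt(5 * 8.75), abs=1e-12)
        assert res.r == pytest.approx(0.9827, abs=5e-5)
        assert res.n == 4

    def test_positive_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r0 = pearson_r(x, y).r
        assert pearson_r(3 * x + 1, 0.5 * y - 2).r == pytest.approx(r0)
        assert pearson_r(-x, y).r == pytest.approx(-r0)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_too_short_rejected(self):
        with pytest.raises(DomainError):
            pearson_r(np.array([1.0, 2.0]), np.array([3.0, 4.0]))


def direct_loglik(beta, y, x):
    eta = beta[0] + beta[1] * x
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


class TestFitLogistic:
    def test_matches_statsmodels_on_toy_data(self):
        fit = fit_logistic(TOY_Y, TOY_X)
        ref = sm.Logit(TOY_Y, sm.add_constant(TOY_X)).fit(disp=0)
        assert fit.coefficients[0] == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.coefficients[1] == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.loglik_model == pytest.approx(ref.llf, abs=1e-8)
        assert fit.loglik_null == pytest.approx(ref.llnull, abs=1e-8)
        assert fit.p_value == pytest.approx(ref.pvalues[1], rel=1e-3)

    def test_matches_direct_likelihood_maximisation(self):
        fit = fit_logistic(TOY_Y, TOY_X)
        res = minimize(
            lambda b: -direct_loglik(b, TOY_Y, TOY_X),
            x0=[0.0, 0.0],
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        assert fit.loglik_model == pytest.approx(-res.fun, abs=1e-6)
        assert fit.coefficients == pytest.approx(res.x, abs=1e-4)

    def test_fit_improves_on_null(self):
        fit = fit_logistic(TOY_Y, TOY_X)
        assert fit.loglik_model >= fit.loglik_null

    def test_ci_brackets_odds_ratio(self):
        fit = fit_logistic(TOY_Y, TOY_X)
        assert fit.ci95_exp_b[0] <= fit.exp_b <= fit.ci95_exp_b[1]

    def test_null_data_recovers_zero_slope(self):
        df = simulate_cohort(CohortSpec(n_cases=2000, intercept=0.3, slope_per_mm3=0.0, seed=7))
        fit = fit_logistic(df.stone_free.to_numpy(), df.true_volume_mm3.to_numpy())
        assert math.log(fit.ci95_exp_b[0]) <= 0.0 <= math.log(fit.ci95_exp_b[1])

    def test_parameter_recovery_at_n2000(self):
        spec = CohortSpec(n_cases=2000, intercept=1.5, slope_per_mm3=-0.006, seed=3)
        df = simulate_cohort(spec)
        fit = fit_logistic(df.stone_free.to_numpy(), df.true_volume_mm3.to_numpy())
        slope, se = fit.coefficients[1], (
            math.log(fit.ci95_exp_b[1]) - math.log(fit.ci95_exp_b[0])
        ) / (2 * 1.96)
        assert abs(slope - (-0.006)) <= 1.96 * se
        assert fit.converged

    def test_complete_separation_flagged(self):
        y = np.array([0.0] * 6 + [1.0] * 6)
        x = np.arange(12.0)
        fit = fit_logistic(y, x)
        assert not fit.converged

    @pytest.mark.parametrize(
        "y,x,err",
        [
            (np.zeros(12), np.arange(12.0), DomainError),  # one class only
            (np.tile([0.0, 1.0], 6), np.ones(12), DomainError),  # constant predictor
            (np.array([0.0, 1.0, 0, 1, 0]), np.arange(5.0), DomainError),  # n < 10
        ],
    )
    def test_degenerate_inputs_rejected(self, y, x, err):
        with pytest.raises(err):
            fit_logistic(y, x)


class TestNagelkerke:
    def test_no_improvement_is_zero(self):
        fit = fit_logistic(TOY_Y, TOY_X)
        degenerate = dataclasses.replace(fit, loglik_model=fit.loglik_null)
        assert nagelkerke_r2(degenerate) == pytest.approx(0.0)

    def test_perfect_model_is_one(self):
        fit = fit_logistic(TOY_Y, TOY_X)
        perfect = dataclasses.replace(fit, loglik_model=0.0)
        assert nagelkerke_r2(perfect) == pytest.approx(1.0)

    def test_matches_brute_force_likelihood_oracle(self):
        # maximise the likelihood over a coefficient grid written in the
        # test, then apply the Cox-Snell / Nagelkerke formulas directly
        n = len(TOY_Y)
        b0s = np.linspace(-6, 6, 241)
        b1s = np.linspace(-2, 2, 241)
        ll1 = max(
            direct_loglik((b0, b1), TOY_Y, TOY_X) for b0 in b0s for b1 in b1s
        )
        p = TOY_Y.mean()
        ll0 = n * (p * math.log(p) + (1 - p) * math.log(1 - p))
        cs = 1 - math.exp((2 / n) * (ll0 - ll1))
        oracle = cs / (1 - math.exp((2 / n) * ll0))
        fit = fit_logistic(TOY_Y, TOY_X)
        assert fit.r2_nagelkerke == pytest.approx(oracle, abs=1e-3)
        assert fit.r2_cox_snell <= fit.r2_nagelkerke
        assert 0 <= fit.r2_nagelkerke <= 1

    def test_invariant_to_class_relabelling(self):
        fit = fit_logistic(TOY_Y, TOY_X)
        flipped = fit_logistic(1 - TOY_Y, TOY_X)
        assert flipped.r2_nagelkerke == pytest.approx(fit.r2_nagelkerke, abs=1e-8)
        assert flipped.coefficients[1] == pytest.approx(-fit.coefficients[1], abs=1e-6)


class TestRankPredictors:
    def test_volume_outranks_noisy_axis(self):
        df = simulate_cohort(CohortSpec(n_cases=2000, intercept=1.0,
                                        slope_per_mm3=-0.006, seed=5))
        rng = np.random.default_rng(6)
        df["noisy_axis_mm"] = df.true_volume_mm3 ** (1 / 3) * np.exp(
            rng.normal(0, 0.3, size=len(df))
        )
        table = rank_predictors(df, ["noisy_axis_mm", "true_volume_mm3"], "stone_free")
        assert table.predictor.iloc[0] == "true_volume_mm3"
        assert table.nagelkerke_r2.is_monotonic_decreasing

    def test_single_predictor(self):
        df = simulate_cohort(CohortSpec(n_cases=500, seed=1))
        table = rank_predictors(df, ["volume_mm3"], "stone_free")
        assert len(table) == 1
        assert set(["p", "exp_b", "ci_low", "ci_high", "nagelkerke_r2"]) <= set(table.columns)

    def test_duplicated_predictor_gets_identical_r2(self):
        df = simulate_cohort(CohortSpec(n_cases=500, seed=2))
        df["volume_copy"] = df.volume_mm3
        table = rank_predictors(df, ["volume_mm3", "volume_copy"], "stone_free")
        r2 = table.set_index("predictor").nagelkerke_r2
        assert r2["volume_mm3"] == pytest.approx(r2["volume_copy"], abs=1e-12)

    def test_missing_column_rejected(self):
        df = simulate_cohort(CohortSpec(n_cases=100, seed=3))
        with pytest.raises(DomainError):
            rank_predictors(df, ["no_such_column"], "stone_free")
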