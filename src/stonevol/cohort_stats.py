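"""Cohort statistics: correlation and stone-free outcome prediction.

Two analyses compare stone-burden measures and link them to treatment
outcome:

* Pearson product-moment correlation between manual and automated
  burden measures.
* Univariable binary logistic regression of the stone-free outcome on
  each burden measure, reported in the convention of clinical
  statistics packages: Wald p-value ("Sig"),
  odds ratio Exp(B) with its 95% Wald CI, and the Cox-Snell and
  Nagelkerke pseudo-R².  Predictors are ranked by Nagelkerke R² —
  the max-rescaled Cox-Snell statistic,

      R²_CS = 1 - exp((2/n) * (L0 - L1))
      R²_N  = R²_CS / (1 - exp((2/n) * L0))

  where L0 and L1 are the log-likelihoods of the intercept-only and
  fitted model.  A higher Nagelkerke R² means the measure explains more
  of the variance in the stone-free outcome.

The logistic fit is a maximum-likelihood Newton / iteratively
reweighted least squares (IRLS) solver; complete separation is flagged
as an unreliable fit rather than silently returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from stonevol.errors import DomainError, UndefinedStatisticError

_MAX_ITER = 100
_TOL = 1e-8


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation between two burden measures."""

    variable_pair: tuple[str, str]
    r: float
    n: int


@dataclass(frozen=True)
class LogisticFit:
    """One univariable logistic model of the stone-free outcome.

    ``coefficients`` is (intercept, slope); ``exp_b`` the odds ratio
    per unit of the predictor with its 95% Wald CI; ``p_value`` the
    Wald test of slope = 0.  ``converged`` is False when the solver hit
    the iteration cap or the data are completely separated, in which
    case the estimates are unreliable.
    """

    predictor: str
    coefficients: tuple[float, float]
    exp_b: float
    ci95_exp_b: tuple[float, float]
    p_value: float
    loglik_null: float
    loglik_model: float
    n: int
    r2_cox_snell: float
    r2_nagelkerke: float
    standard_errors: tuple[float, float] = (float("nan"), float("nan"))
    converged: bool = True


def pearson_r(
    x: np.ndarray, y: np.ndarray, labels: tuple[str, str] = ("x", "y")
) -> CorrelationResult:
    """Pearson product-moment correlation.

    Requires equal-length vectors of at least 3 observations, neither
    constant (the correlation is undefined for zero variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError(f"vectors must be 1D of equal length, got {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise DomainError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    r = float(sps.pearsonr(x, y).statistic)
    return CorrelationResult(variable_pair=labels, r=r, n=len(x))


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log(1+exp(eta)) via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _null_loglik(y: np.ndarray) -> float:
    n, k = len(y), int(y.sum())
    if k == 0 or k == n:
        return 0.0
    p = k / n
    return k * math.log(p) + (n - k) * math.log(1.0 - p)


def fit_logistic(outcome: np.ndarray, predictor: np.ndarray, label: str = "x") -> LogisticFit:
    """Fit a univariable binary logistic model by IRLS.

    ``outcome`` is 0/1 (1 = stone-free); both classes must be present
    and n >= 10.  Convergence when the largest coefficient change falls
    below 1e-8, capped at 100 iterations.  Complete or quasi-complete
    separation (diverging coefficients) yields ``converged=False``.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise DomainError("outcome and predictor must be 1D of equal length")
    n = len(y)
    if n < 10:
        raise DomainError(f"need at least 10 observations, got {n}")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise DomainError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise DomainError("both outcome classes must be present")
    if np.ptp(x) == 0:
        raise DomainError("predictor is constant")

    # center+scale internally for conditioning; back-transform after
    mu, sd = x.mean(), x.std()
    z = (x - mu) / sd
    X = np.column_stack([np.ones(n), z])

    beta = np.zeros(2)
    converged = False
    for _ in range(_MAX_ITER):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        # Newton step == IRLS with working response
        XtWX = X.T @ (X * w[:, None])
        grad = X.T @ (y - p)
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < _TOL:
            converged = True
            break

    # separation heuristic: standardized slope magnitude diverging
    if converged and abs(beta[1]) > 30:
        converged = False

    eta = X @ beta
    loglik_model = _bernoulli_loglik(y, eta)
    loglik_null = _null_loglik(y)

    intercept = beta[0] - beta[1] * mu / sd
    slope = beta[1] / sd

    p_hat = 1.0 / (1.0 + np.exp(-eta))
    w = p_hat * (1.0 - p_hat)
    Xr = np.column_stack([np.ones(n), x])
    XtWX = Xr.T @ (Xr * w[:, None])
    try:
        cov = np.linalg.inv(XtWX)
        se_intercept = math.sqrt(max(cov[0, 0], 0.0))
        se_slope = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se_intercept = se_slope = math.inf
    def safe_exp(v: float) -> float:
        try:
            return math.exp(v)
        except OverflowError:
            return math.inf

    if se_slope > 0 and math.isfinite(se_slope):
        zstat = slope / se_slope
        p_value = 2.0 * sps.norm.sf(abs(zstat))
        ci = (safe_exp(slope - 1.96 * se_slope), safe_exp(slope + 1.96 * se_slope))
    else:
        p_value = float("nan")
        ci = (float("nan"), float("nan"))

    r2_cs, r2_n = _pseudo_r2(loglik_null, loglik_model, n)
    return LogisticFit(
        predictor=label,
        coefficients=(intercept, slope),
        exp_b=safe_exp(slope),
        ci95_exp_b=ci,
        p_value=float(p_value),
        loglik_null=loglik_null,
        loglik_model=loglik_model,
        n=n,
        r2_cox_snell=r2_cs,
        r2_nagelkerke=r2_n,
        standard_errors=(se_intercept, se_slope),
        converged=converged,
    )


def _pseudo_r2(loglik_null: float, loglik_model: float, n: int) -> tuple[float, float]:
    r2_cs = 1.0 - math.exp((2.0 / n) * (loglik_null - loglik_model))
    max_cs = 1.0 - math.exp((2.0 / n) * loglik_null)
    r2_n = r2_cs / max_cs if max_cs > 0 else 0.0
    return r2_cs, r2_n


def nagelkerke_r2(fit: LogisticFit) -> float:
    """Nagelkerke (max-rescaled Cox-Snell) R² from a fit's log-likelihoods."""
    return _pseudo_r2(fit.loglik_null, fit.loglik_model, fit.n)[1]


def rank_predictors(
    cohort: pd.DataFrame, predictors: list[str], outcome: str = "stone_free"
) -> pd.DataFrame:
    """Fit one univariable logistic model per predictor and rank them.

    Returns a table with one row per predictor — Sig (Wald p), Exp(B),
    its 95% CI and Nagelkerke R² — sorted by Nagelkerke R² descending.
    """
    missing = [c for c in predictors + [outcome] if c not in cohort.columns]
    if missing:
        raise DomainError(f"columns absent from cohort table: {missing}")
    rows = []
    for name in predictors:
        fit = fit_logistic(cohort[outcome].to_numpy(), cohort[name].to_numpy(), label=name)
        rows.append(
            {
                "predictor": name,
                "p": fit.p_value,
                "exp_b": fit.exp_b,
                "ci_low": fit.ci95_exp_b[0],
                "ci_high": fit.ci95_exp_b[1],
                "nagelkerke_r2": fit.r2_nagelkerke,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows).sort_values("nagelkerke_r2", ascending=False, kind="stable")
    return table.reset_index(drop=True)
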