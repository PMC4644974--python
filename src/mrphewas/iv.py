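"""Instrumental-variable follow-up of stage-1 hits.

Continuous outcomes get two-stage least squares with the allele score as the
single instrument for the (log-transformed, standardized) exposure, with the
heteroskedasticity-robust sandwich computed on the structural IV residuals
y - X b (not the second-stage fitted-regressor residuals, which is a known
error). Binary outcomes get the two-stage logistic procedure: OLS first
stage, then logistic regression of the outcome on first-stage fitted values
with robust SEs — whose SEs do not propagate first-stage uncertainty, a
property of the procedure that is recorded on the result. Endogeneity of the
observational estimate is tested with a robust control-function
Durbin-Wu-Hausman test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .io import DataError
from .transforms import AlleleScore

_ZCRIT = stats.norm.ppf(0.975)
MIN_FIRST_STAGE_N = 30
SEPARATION_COEF = 15.0


def _as_vector(x) -> np.ndarray:
    if isinstance(x, AlleleScore):
        x = x.values
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise DataError("expected a 1-D vector")
    return x


def _complete_cases(*vectors) -> np.ndarray:
    mask = np.ones(len(vectors[0]), dtype=bool)
    for v in vectors:
        if v.ndim == 1:
            mask &= ~np.isnan(v)
        else:
            mask &= ~np.isnan(v).any(axis=1)
    return mask


@dataclass
class FirstStageResult:
    """Exposure-on-instrument regression: instrument strength diagnostics."""

    fitted: np.ndarray
    F: float
    beta: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    weak_sample_warning: bool = False


@dataclass
class IvEstimate:
    """One stage-2 result row.

    ``estimate`` is the SD change of the prepared outcome per 1 SD of the
    exposure for linear models, and the odds ratio per 1 SD of exposure for
    logistic ones (CI on the same scale).
    """

    outcome_name: str
    kind: str  # "linear" | "logistic"
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    first_stage_F: float
    dwh_p: float = float("nan")
    observational: dict = field(default_factory=dict)
    notes: str = ""


def first_stage(exposure, score) -> FirstStageResult:
    """OLS of the exposure on the score; F is the squared t of the slope."""
    x = _as_vector(exposure)
    s = _as_vector(score)
    ok = _complete_cases(x, s)
    n = int(ok.sum())
    if n < 3:
        raise DataError("first stage needs at least 3 complete cases")
    fit = sm.OLS(x[ok], sm.add_constant(s[ok])).fit()
    t = fit.tvalues[1]
    F = float(min(t * t, 1e12)) if np.isfinite(t) else 1e12
    ci = fit.conf_int()[1]
    fitted = np.full(len(x), np.nan)
    fitted[ok] = fit.fittedvalues
    return FirstStageResult(fitted=fitted, F=F, beta=float(fit.params[1]),
                            se=float(fit.bse[1]), ci_low=float(ci[0]),
                            ci_high=float(ci[1]), n=n,
                            weak_sample_warning=n < MIN_FIRST_STAGE_N)


class TwoStageLeastSquares(BaseEstimator):
    """2SLS with a single endogenous exposure and one or more instruments.

    fit(exposure, outcome, instruments) solves the standard IV normal
    equations with an intercept and stores the heteroskedasticity-robust
    sandwich computed on the IV residuals.

    Attributes: ``estimate_``, ``se_``, ``ci_``, ``p_value_``, ``n_``,
    ``first_stage_F_`` (single-instrument: squared first-stage t).
    """

    def __init__(self, robust: bool = True):
        self.robust = robust

    def fit(self, exposure, outcome, instruments):
        x = _as_vector(exposure)
        y = _as_vector(outcome)
        Z = instruments.values if isinstance(instruments, AlleleScore) \
            else np.asarray(instruments, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        ok = _complete_cases(x, y, Z)
        x, y, Z = x[ok], y[ok], Z[ok]
        n = len(y)
        if n < 3:
            raise DataError("2SLS needs at least 3 complete cases")

        fs = first_stage(x, Z[:, 0]) if Z.shape[1] == 1 else None
        Zc = np.column_stack([np.ones(n), Z])
        Xc = np.column_stack([np.ones(n), x])
        # projection of X onto the instrument span
        ZtZ = Zc.T @ Zc
        Xhat = Zc @ np.linalg.solve(ZtZ, Zc.T @ Xc)
        XhX = Xhat.T @ Xc
        if abs(np.linalg.det(XhX)) < 1e-12 * n**2:
            raise DataError("weak/degenerate instrument: no first-stage signal")
        beta = np.linalg.solve(XhX, Xhat.T @ y)
        e = y - Xc @ beta  # structural IV residuals
        XhX_inv = np.linalg.inv(XhX)
        if self.robust:
            meat = (Xhat * e[:, None] ** 2).T @ Xhat
            V = XhX_inv @ meat @ XhX_inv.T
        else:
            V = XhX_inv @ (Xhat.T @ Xhat) @ XhX_inv.T * (e @ e / n)
        self.coef_ = beta
        self.estimate_ = float(beta[1])
        self.se_ = float(np.sqrt(V[1, 1]))
        self.ci_ = (self.estimate_ - _ZCRIT * self.se_,
                    self.estimate_ + _ZCRIT * self.se_)
        self.p_value_ = float(2 * stats.norm.sf(abs(self.estimate_ / self.se_)))
        self.n_ = n
        if fs is not None:
            self.first_stage_F_ = fs.F
        else:
            fit_fs = sm.OLS(x, Zc).fit()
            hyp = np.zeros((Z.shape[1], Zc.shape[1]))
            hyp[:, 1:] = np.eye(Z.shape[1])
            self.first_stage_F_ = float(fit_fs.f_test(hyp).fvalue)
        if self.first_stage_F_ < 1e-8:
            raise DataError("weak/degenerate instrument: first-stage F ~ 0")
        return self

    def predict(self, exposure) -> np.ndarray:
        x = _as_vector(exposure)
        return self.coef_[0] + self.coef_[1] * x


class TwoStageLogistic(BaseEstimator):
    """Two-stage procedure for binary outcomes.

    Stage one regresses the exposure on the instrument by OLS; stage two is a
    logistic regression of the outcome on the first-stage fitted values with
    a robust sandwich covariance. The reported SEs do not propagate
    first-stage uncertainty — faithful to the procedure this mirrors.

    Attributes: ``or_`` (odds ratio per 1 SD exposure), ``coef_`` (log OR),
    ``se_``, ``ci_`` (OR scale), ``p_value_``, ``n_``, ``first_stage_F_``.
    """

    def __init__(self, cov_type: str = "HC1"):
        self.cov_type = cov_type

    def fit(self, exposure, outcome, instruments):
        x = _as_vector(exposure)
        y = _as_vector(outcome)
        s = instruments.values if isinstance(instruments, AlleleScore) \
            else np.asarray(instruments, dtype=float)
        if s.ndim != 1:
            raise DataError("two-stage logistic expects a single score instrument")
        ok = _complete_cases(x, y, s)
        x, y, s = x[ok], y[ok], s[ok]
        classes = np.unique(y)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise DataError(
                f"binary outcome must contain both classes coded 0/1, got {classes}")
        fs = first_stage(x, s)
        fitted = fs.fitted
        res = sm.Logit(y, sm.add_constant(fitted)).fit(
            disp=0, cov_type=self.cov_type)
        coef, se = float(res.params[1]), float(res.bse[1])
        if abs(coef) > SEPARATION_COEF:
            raise DataError("separation detected in second-stage logistic")
        self.coef_ = coef
        self.se_ = se
        self.or_ = float(np.exp(coef))
        self.ci_ = (float(np.exp(coef - _ZCRIT * se)),
                    float(np.exp(coef + _ZCRIT * se)))
        self.p_value_ = float(2 * stats.norm.sf(abs(coef / se)))
        self.n_ = len(y)
        self.first_stage_F_ = fs.F
        return self


def tsls_linear(outcome, exposure, score, outcome_name: str = "") -> IvEstimate:
    """Single-instrument 2SLS wrapper returning an :class:`IvEstimate`."""
    model = TwoStageLeastSquares().fit(exposure, outcome, score)
    return IvEstimate(outcome_name=outcome_name, kind="linear",
                      estimate=model.estimate_, ci_low=model.ci_[0],
                      ci_high=model.ci_[1], p_value=model.p_value_,
                      n=model.n_, first_stage_F=model.first_stage_F_)


def two_stage_logistic(outcome, exposure, score,
                       outcome_name: str = "") -> IvEstimate:
    """Two-stage logistic wrapper; estimate is the odds ratio per 1 SD."""
    model = TwoStageLogistic().fit(exposure, outcome, score)
    return IvEstimate(outcome_name=outcome_name, kind="logistic",
                      estimate=model.or_, ci_low=model.ci_[0],
                      ci_high=model.ci_[1], p_value=model.p_value_,
                      n=model.n_, first_stage_F=model.first_stage_F_,
                      notes="second-stage SEs ignore first-stage uncertainty")


def dwh_test(outcome, exposure, score) -> float:
    """Robust control-function Durbin-Wu-Hausman endogeneity test.

    The first-stage residual is appended to the observational outcome model;
    a robust t-test on its coefficient tests whether the IV and observational
    estimates differ. Returns the two-sided p (NaN if the exposure is fully
    determined by the score, when the residual is degenerate).
    """
    y = _as_vector(outcome)
    x = _as_vector(exposure)
    s = _as_vector(score)
    ok = _complete_cases(y, x, s)
    y, x, s = y[ok], x[ok], s[ok]
    fs = sm.OLS(x, sm.add_constant(s)).fit()
    resid = x - fs.fittedvalues
    if np.var(resid) < 1e-12 * max(np.var(x), 1e-30):
        return float("nan")
    X = np.column_stack([np.ones(len(y)), x, resid])
    fit = sm.OLS(y, X).fit(cov_type="HC1")
    t = fit.params[2] / fit.bse[2]
    return float(2 * stats.t.sf(abs(t), df=len(y) - 3))


def observational_estimate(outcome, exposure, kind: str = "linear") -> dict:
    """Direct regression of the outcome on the exposure with robust SEs.

    Linear: OLS slope with HC1 SE and t(n-2) p. Logistic: odds ratio per
    1 SD of exposure with robust sandwich.
    """
    y = _as_vector(outcome)
    x = _as_vector(exposure)
    ok = _complete_cases(y, x)
    y, x = y[ok], x[ok]
    n = len(y)
    X = sm.add_constant(x)
    if kind == "linear":
        fit = sm.OLS(y, X).fit(cov_type="HC1")
        b, se = float(fit.params[1]), float(fit.bse[1])
        p = float(2 * stats.t.sf(abs(b / se), df=n - 2))
        return {"estimate": b, "ci_low": b - _ZCRIT * se,
                "ci_high": b + _ZCRIT * se, "p": p, "n": n}
    if kind == "logistic":
        classes = np.unique(y)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise DataError("binary outcome must contain both classes coded 0/1")
        fit = sm.Logit(y, X).fit(disp=0, cov_type="HC1")
        b, se = float(fit.params[1]), float(fit.bse[1])
        return {"estimate": float(np.exp(b)),
                "ci_low": float(np.exp(b - _ZCRIT * se)),
                "ci_high": float(np.exp(b + _ZCRIT * se)),
                "p": float(2 * stats.norm.sf(abs(b / se))), "n": n}
    raise DataError(f"unknown model kind {kind!r}")
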