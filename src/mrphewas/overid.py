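"""Instrument-validity diagnostics.

With more instruments than endogenous regressors the IV model is
over-identified and the instruments can be played off against each other:
if they all act on the outcome only through the exposure they must imply the
same causal effect. The continuously-updating GMM estimator (CUE) minimises
the robust GMM objective J(b) with the weight matrix recomputed at every
candidate b; the minimised J is Hansen's over-identification statistic,
asymptotically chi-square with (#instruments - 1) degrees of freedom under
instrument validity.

The model here has exactly one endogenous regressor and no covariates, so
the intercept is partialled out by centering all variables and the CUE
objective is minimised in one dimension, bracketing the 2SLS estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .io import Cohort, DataError, SnpWeightTable
from .iv import IvEstimate, _as_vector, _complete_cases, tsls_linear, two_stage_logistic
from .transforms import build_allele_score

logger = logging.getLogger("mrphewas")

_BRACKET_SE_MULT = 10.0
_MAX_EXPANSIONS = 3
_XTOL = 1e-10


@dataclass
class OveridResult:
    """CUE point estimate with the Hansen J over-identification test."""

    outcome_name: str
    beta_cue: float
    se_cue: float
    j_stat: float
    df: int
    p_j: float
    n: int
    weight_ridged: bool = False


class CUEGMM(BaseEstimator):
    """Continuously-updating GMM for one endogenous regressor.

    Moments are g_i(b) = z_i (y_i - b x_i) on centered y, x, z. The weight
    matrix W(b) = (1/n) sum g g' - g-bar g-bar' (centered robust convention;
    the uncentered variant behind ``center_weight=False``) is continuously
    updated inside the objective J(b) = n g-bar' W(b)^{-1} g-bar.

    Attributes: ``beta_``, ``se_``, ``j_stat_``, ``df_``, ``p_j_``, ``n_``,
    ``weight_ridged_`` (True when a singular W needed a ridge).
    """

    def __init__(self, center_weight: bool = True, xtol: float = _XTOL):
        self.center_weight = center_weight
        self.xtol = xtol

    def fit(self, exposure, outcome, instruments):
        x = _as_vector(exposure)
        y = _as_vector(outcome)
        Z = np.asarray(instruments, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        ok = _complete_cases(x, y, Z)
        x, y, Z = x[ok], y[ok], Z[ok]
        n, L = Z.shape
        if n < L + 2:
            raise DataError("too few observations for the instrument count")
        x = x - x.mean()
        y = y - y.mean()
        Z = Z - Z.mean(axis=0)

        # g_i(b) = a_i - b * c_i with a_i = z_i y_i, c_i = z_i x_i; all the
        # moments of J(b) reduce to fixed LxL cross-products.
        A = Z * y[:, None]
        C = Z * x[:, None]
        abar, cbar = A.mean(axis=0), C.mean(axis=0)
        AA, AC, CC = A.T @ A / n, A.T @ C / n, C.T @ C / n
        self._ridged = False

        def gbar(b):
            return abar - b * cbar

        def weight(b):
            W = AA - b * (AC + AC.T) + b * b * CC
            if self.center_weight:
                g = gbar(b)
                W = W - np.outer(g, g)
            return W

        def objective(b):
            g = gbar(b)
            W = weight(b)
            try:
                sol = np.linalg.solve(W, g)
            except np.linalg.LinAlgError:
                sol = None
            if sol is None or not np.all(np.isfinite(sol)):
                ridge = 1e-10 * np.trace(W) / L
                logger.info("singular CUE weight at b=%g; ridge %g added", b, ridge)
                self._ridged = True
                sol = np.linalg.solve(W + ridge * np.eye(L), g)
            return n * float(g @ sol)

        # condition check once: near-singular W triggers the ridge path
        if np.linalg.cond(weight(0.0)) > 1e12:
            self._ridged = True

        denom = float(cbar @ np.linalg.solve(Z.T @ Z / n, cbar))
        if denom < 1e-12:
            raise DataError("weak/degenerate instruments: no first-stage signal")
        b2sls = float(cbar @ np.linalg.solve(Z.T @ Z / n, abar)) / denom
        # rough 2SLS scale for the bracket
        e = y - b2sls * x
        xhat = Z @ np.linalg.solve(Z.T @ Z, Z.T @ x)
        se2sls = float(np.sqrt((xhat**2 @ e**2) / (xhat @ x) ** 2))
        half = max(_BRACKET_SE_MULT * se2sls, 1e-6 * max(abs(b2sls), 1.0))

        beta = None
        for attempt in range(_MAX_EXPANSIONS + 1):
            lo, hi = b2sls - half, b2sls + half
            res = optimize.minimize_scalar(objective, bounds=(lo, hi),
                                           method="bounded",
                                           options={"xatol": self.xtol})
            width = hi - lo
            if (res.x - lo > 1e-3 * width) and (hi - res.x > 1e-3 * width):
                beta = float(res.x)
                break
            half *= 4.0
        if beta is None:
            raise DataError("CUE minimum not interior after bracket expansions")

        g = gbar(beta)
        W = weight(beta)
        if self._ridged:
            W = W + 1e-10 * np.trace(W) / L * np.eye(L)
        Winv_g = np.linalg.solve(W, g)
        self.j_stat_ = max(n * float(g @ Winv_g), 0.0)
        self.beta_ = beta
        self.df_ = L - 1
        self.p_j_ = float(stats.chi2.sf(self.j_stat_, self.df_)) \
            if self.df_ > 0 else float("nan")
        G = -cbar  # d g-bar / d b
        avar = 1.0 / (n * float(G @ np.linalg.solve(W, G)))
        self.se_ = float(np.sqrt(avar))
        self.n_ = n
        self.beta_2sls_ = b2sls
        self.weight_ridged_ = self._ridged
        self.objective_ = objective
        return self


def cue_gmm(outcome, exposure, instruments, outcome_name: str = "",
            center_weight: bool = True) -> OveridResult:
    """CUE point estimate and Hansen J test (functional wrapper)."""
    model = CUEGMM(center_weight=center_weight).fit(exposure, outcome, instruments)
    return OveridResult(outcome_name=outcome_name, beta_cue=model.beta_,
                        se_cue=model.se_, j_stat=model.j_stat_, df=model.df_,
                        p_j=model.p_j_, n=model.n_,
                        weight_ridged=model.weight_ridged_)


@dataclass
class SplitComparison:
    """Estimates from two disjoint sub-instruments plus their Hansen test."""

    outcome_name: str
    single_snp: str
    estimate_single: IvEstimate
    estimate_rest: IvEstimate
    hansen_split_p: float


def effect_allele_dosages(cohort: Cohort, weights: SnpWeightTable) -> np.ndarray:
    """Dosage matrix oriented to count effect alleles for every weight-table SNP."""
    cols = []
    for snp, effect, other in zip(weights.snp_ids,
                                  weights.table["effect_allele"],
                                  weights.table["other_allele"]):
        if snp not in cohort.dosages.columns:
            raise DataError(f"SNP {snp} absent from cohort")
        g = cohort.dosages[snp].to_numpy(dtype=float)
        counted = cohort.counted_allele.get(snp)
        if counted == effect:
            cols.append(g)
        elif counted == other:
            cols.append(2.0 - g)
        else:
            raise DataError(f"counted allele for {snp} matches neither allele")
    return np.column_stack(cols)


def split_instrument_compare(outcome, exposure, cohort: Cohort,
                             weights: SnpWeightTable, single_snp: str,
                             kind: str = "linear",
                             outcome_name: str = "") -> SplitComparison:
    """Compare IV estimates from one singled-out SNP vs the score of the rest.

    Two instruments acting only through the exposure must agree; the Hansen
    p from CUE with the two sub-scores as joint instruments (df = 1)
    quantifies their disagreement.
    """
    if single_snp not in weights.snp_ids:
        raise DataError(f"SNP {single_snp!r} not in weight table")
    if len(weights.snp_ids) < 2:
        raise DataError("split comparison needs at least 2 SNPs")
    score_single = build_allele_score(cohort, weights, subset=[single_snp])
    rest_ids = [s for s in weights.snp_ids if s != single_snp]
    score_rest = build_allele_score(cohort, weights, subset=rest_ids)

    fit_fun = tsls_linear if kind == "linear" else two_stage_logistic
    est_single = fit_fun(outcome, exposure, score_single, outcome_name=outcome_name)
    est_rest = fit_fun(outcome, exposure, score_rest, outcome_name=outcome_name)
    Z = np.column_stack([score_single.values, score_rest.values])
    hansen = cue_gmm(outcome, exposure, Z, outcome_name=outcome_name)
    return SplitComparison(outcome_name=outcome_name, single_snp=single_snp,
                           estimate_single=est_single, estimate_rest=est_rest,
                           hansen_split_p=hansen.p_j)
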