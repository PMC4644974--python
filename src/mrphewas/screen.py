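"""Stage-1 phenome-wide screen of the allele score against every outcome.

Each outcome is inverse-normal transformed on its own complete cases and
regressed on the standardized score with heteroskedasticity-robust standard
errors. Results are ranked by p-value (rank 1 = strongest), Bonferroni
adjusted over the non-validation outcomes, and summarised with the plug-in
false discovery rate, QQ data and confounder balance checks.

The regression core is vectorised across outcomes via sufficient-statistic
accumulation, which makes the permutation engine affordable; it is verified
against statsmodels' sandwich estimators in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

import statsmodels.api as sm

from .io import Cohort, DataError, PipelineConfig
from .transforms import AlleleScore, RankInverseNormal

MIN_COMPLETE_CASES = 10


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def univariate_robust_screen(score: np.ndarray, Y: np.ndarray,
                             flavor: str = "HC1",
                             min_complete: int = MIN_COMPLETE_CASES
                             ) -> pd.DataFrame:
    """Per-column OLS of Y on [1, score] with robust SEs, vectorised.

    Y may contain NaN; each column uses its own complete cases. Returns a
    frame with columns n, gamma_hat, robust_se, p_value (NaN where the column
    was skipped for too few cases or zero variance).
    """
    s = np.asarray(score, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or len(s) != Y.shape[0]:
        raise DataError("score and outcome matrix are not aligned")
    if flavor == "HC3":
        return _screen_loop_hc3(s, Y, min_complete)

    M = (~np.isnan(Y)).astype(float)
    Y0 = np.nan_to_num(Y)
    Y0sq = Y0 * Y0
    s1, s2, s3, s4 = s, s**2, s**3, s**4

    N = M.sum(axis=0)
    S1, S2, S3, S4 = s1 @ M, s2 @ M, s3 @ M, s4 @ M
    T01, T11, T21, T31 = Y0.sum(axis=0), s1 @ Y0, s2 @ Y0, s3 @ Y0
    T02, T12, T22 = Y0sq.sum(axis=0), s1 @ Y0sq, s2 @ Y0sq

    with np.errstate(divide="ignore", invalid="ignore"):
        det = N * S2 - S1**2
        b = (N * T11 - S1 * T01) / det
        a = (T01 - b * S1) / N
        # sum over complete cases of s^p * residual^2, p = 0, 1, 2
        E0 = T02 + a**2 * N + b**2 * S2 - 2 * a * T01 - 2 * b * T11 + 2 * a * b * S1
        E1 = T12 + a**2 * S1 + b**2 * S3 - 2 * a * T11 - 2 * b * T21 + 2 * a * b * S2
        E2 = T22 + a**2 * S2 + b**2 * S4 - 2 * a * T21 - 2 * b * T31 + 2 * a * b * S3
        var_b = (S1**2 * E0 - 2 * S1 * N * E1 + N**2 * E2) / det**2
        if flavor == "HC1":
            var_b = var_b * N / (N - 2)
        elif flavor != "HC0":
            raise DataError(f"unknown robust SE flavor {flavor!r}")
        se = np.sqrt(var_b)
        var_y = T02 / N - (T01 / N) ** 2
        var_s = S2 / N - (S1 / N) ** 2
        ok = (N >= min_complete) & (var_y > 1e-14) & (var_s > 1e-14)
        t = b / se
        p = 2 * stats.t.sf(np.abs(t), df=np.maximum(N - 2, 1))
        p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = pd.DataFrame({"n": N.astype(int), "gamma_hat": b,
                        "robust_se": se, "p_value": p})
    out.loc[~ok, ["gamma_hat", "robust_se", "p_value"]] = np.nan
    return out


def _screen_loop_hc3(s: np.ndarray, Y: np.ndarray,
                     min_complete: int) -> pd.DataFrame:
    """HC3 needs per-observation leverages; plain per-outcome loop."""
    rows = []
    for j in range(Y.shape[1]):
        y = Y[:, j]
        ok = ~np.isnan(y)
        n = int(ok.sum())
        if n < min_complete or np.var(y[ok]) <= 1e-14 or np.var(s[ok]) <= 1e-14:
            rows.append((n, np.nan, np.nan, np.nan))
            continue
        X = sm.add_constant(s[ok])
        res = sm.OLS(y[ok], X).fit(cov_type="HC3")
        b, se = res.params[1], res.bse[1]
        p = 2 * stats.t.sf(abs(b / se), df=n - 2)
        rows.append((n, b, se, p))
    return pd.DataFrame(rows, columns=["n", "gamma_hat", "robust_se", "p_value"])


def rank_results(records: pd.DataFrame) -> pd.DataFrame:
    """Rank by ascending p (rank 1 = strongest); ties broken by descending
    |gamma_hat| then outcome name. Skipped records (NaN p) stay unranked."""
    out = records.copy()
    ranked = out[out["p_value"].notna()].copy()
    ranked["_abs"] = -ranked["gamma_hat"].abs()
    order = ranked.sort_values(["p_value", "_abs", "outcome"],
                               kind="mergesort").index
    out["rank"] = np.nan
    out.loc[order, "rank"] = np.arange(1, len(order) + 1)
    return out


def bonferroni_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Bonferroni-adjusted p: min(1, p * m)."""
    if m < 1:
        raise DataError("Bonferroni m must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * m)[()]


@dataclass(frozen=True)
class MultiplicityContext:
    """Counts behind the multiplicity summaries: m non-validation outcomes
    tested, threshold alpha, and k of them observed with p < alpha."""

    m: int
    alpha: float
    k: int

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.m:
            raise DataError(f"need 0 <= k <= m, got k={self.k}, m={self.m}")

    @property
    def expected_by_chance(self) -> float:
        return self.m * self.alpha


def estimate_fdr(ctx: MultiplicityContext) -> float:
    """Plug-in FDR: expected chance count m*alpha over observed count k,
    capped at 1. Returns NaN when k = 0 (nothing to follow up)."""
    if ctx.k == 0:
        return float("nan")
    return min(1.0, ctx.expected_by_chance / ctx.k)


def test_of_proportions(k1: int, n1: int, p0_or_k2n2) -> float:
    """Two-sided z test of proportions, no continuity correction.

    One-sample form: third argument is the null proportion p0. Two-sample
    form: third argument is a (k2, n2) pair and a pooled-variance z is used.
    """
    if n1 <= 0:
        raise DataError("n must be positive")
    p1 = k1 / n1
    if np.isscalar(p0_or_k2n2):
        p0 = float(p0_or_k2n2)
        z = (p1 - p0) / np.sqrt(p0 * (1 - p0) / n1)
    else:
        k2, n2 = p0_or_k2n2
        if n2 <= 0:
            raise DataError("n must be positive")
        p2 = k2 / n2
        pooled = (k1 + k2) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    return float(2 * stats.norm.sf(abs(z)))


def qq_data(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Expected vs observed -log10 p for the QQ plot.

    Expected quantile for ascending rank i of m is i/(m+1). The frame's
    ``attrs['bonferroni_threshold']`` carries alpha/m for the reference line.
    """
    p = records["p_value"].dropna().sort_values().to_numpy()
    m = len(p)
    if m == 0:
        raise DataError("no p-values for QQ data")
    expected = np.arange(1, m + 1) / (m + 1)
    out = pd.DataFrame({"expected_neglog10_p": -np.log10(expected),
                        "observed_neglog10_p": -np.log10(p)})
    out.attrs["bonferroni_threshold"] = alpha / m
    return out


class PhenomeScreen(BaseEstimator):
    """Phenome-wide robust-regression screen of an allele score.

    Parameters
    ----------
    alpha : float
        Nominal screening threshold used in the multiplicity summaries.
    int_offset : float
        Rank offset of the inverse normal transform (0 = r/(n+1)).
    robust_se_flavor : {"HC0", "HC1", "HC3"}
        Sandwich flavour; HC1 reproduces common software defaults.
    min_complete : int
        Outcomes with fewer complete cases are skipped (flagged, not dropped).
    seed : int
        Seed for the transform's tie-break randomisation.
    bonferroni_m : int or None
        Override for the Bonferroni multiplier; default counts the
        non-validation outcomes actually tested.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per outcome: n, gamma_hat, robust_se, p_value, ci bounds,
        rank, p_bonferroni, validation_set, skipped/skip_reason.
    int_matrix_ : ndarray
        The inverse-normal-transformed phenotype matrix (frozen tie-breaks),
        reused by the permutation engine.
    multiplicity_ : MultiplicityContext
    fdr_ : float
    """

    def __init__(self, alpha: float = 0.05, int_offset: float = 0.0,
                 robust_se_flavor: str = "HC1",
                 min_complete: int = MIN_COMPLETE_CASES,
                 seed: int = 0, bonferroni_m: int | None = None):
        self.alpha = alpha
        self.int_offset = int_offset
        self.robust_se_flavor = robust_se_flavor
        self.min_complete = min_complete
        self.seed = seed
        self.bonferroni_m = bonferroni_m

    def fit(self, score: AlleleScore | np.ndarray, cohort: Cohort):
        s = score.values if isinstance(score, AlleleScore) else np.asarray(score)
        if len(s) != cohort.n_individuals:
            raise DataError("score length does not match cohort size")
        Y = cohort.phenotypes.to_numpy(dtype=float)
        names = cohort.outcome_names
        validation = cohort.validation_flags().to_numpy(dtype=bool)

        transformer = RankInverseNormal(offset=self.int_offset, seed=self.seed,
                                        min_nonmissing=self.min_complete)
        self.int_matrix_ = transformer.fit_transform(Y)

        res = univariate_robust_screen(s, self.int_matrix_,
                                       flavor=self.robust_se_flavor,
                                       min_complete=self.min_complete)
        res.insert(0, "outcome", names)
        res["validation_set"] = validation
        res["skipped"] = res["p_value"].isna()
        reasons = np.where(res["n"] < self.min_complete,
                           "fewer than %d complete cases" % self.min_complete,
                           "zero variance after transform")
        res["skip_reason"] = np.where(res["skipped"], reasons, "")
        zcrit = stats.norm.ppf(0.975)
        res["ci_low"] = res["gamma_hat"] - zcrit * res["robust_se"]
        res["ci_high"] = res["gamma_hat"] + zcrit * res["robust_se"]

        res = rank_results(res)
        tested = res["p_value"].notna() & ~res["validation_set"]
        m = self.bonferroni_m if self.bonferroni_m else int(tested.sum())
        res["p_bonferroni"] = np.nan
        if m >= 1 and tested.any():
            res.loc[tested, "p_bonferroni"] = bonferroni_adjust(
                res.loc[tested, "p_value"].to_numpy(), m)
        k = int((res.loc[tested, "p_value"] < self.alpha).sum())
        self.multiplicity_ = MultiplicityContext(m=max(m, k), alpha=self.alpha, k=k)
        self.fdr_ = estimate_fdr(self.multiplicity_)
        self.score_ = s
        self.results_ = res
        return self

    def qq_data(self) -> pd.DataFrame:
        return qq_data(self.results_, alpha=self.alpha)


def screen_outcomes(score: AlleleScore | np.ndarray, cohort: Cohort,
                    config: PipelineConfig) -> pd.DataFrame:
    """Functional wrapper over :class:`PhenomeScreen` (one row per outcome)."""
    screen = PhenomeScreen(alpha=config.alpha, int_offset=config.int_offset,
                           robust_se_flavor=config.robust_se_flavor,
                           seed=_seed_int(config.child_seed("int")),
                           bonferroni_m=config.bonferroni_m)
    return screen.fit(score, cohort).results_


def confounder_balance(score: AlleleScore | np.ndarray,
                       exposure: np.ndarray,
                       confounders: pd.DataFrame,
                       ordinal: dict[str, bool] | None = None) -> pd.DataFrame:
    """Balance checks of score and exposure against candidate confounders.

    For each categorical confounder, the standardized score (and separately
    the exposure) is regressed on indicator contrasts against the first
    (reference) level, giving per-level estimates with 95% CIs. The per-
    confounder p is a linear-trend p (regression on integer level codes) for
    ordinal confounders with more than two levels, the contrast p for binary
    ones, and a joint Wald p otherwise. Single-level confounders are skipped.
    """
    s = score.values if isinstance(score, AlleleScore) else np.asarray(score)
    exposure = np.asarray(exposure, dtype=float)
    ordinal = ordinal or {}
    rows = []
    for name in confounders.columns:
        c = confounders[name]
        for target_name, target in (("score", s), ("exposure", exposure)):
            ok = c.notna().to_numpy() & ~np.isnan(target)
            levels = pd.unique(c[ok])
            try:
                levels = np.sort(levels)  # ordinal coding needs sorted levels
            except TypeError:
                pass
            if len(levels) < 2:
                rows.append({"confounder": name, "target": target_name,
                             "level": "", "n": int(ok.sum()),
                             "estimate": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "p": np.nan,
                             "note": "single level: skipped"})
                continue
            codes = pd.Categorical(c[ok], categories=list(levels))
            dummies = pd.get_dummies(codes, drop_first=True).to_numpy(float)
            y = target[ok]
            X = sm.add_constant(dummies)
            fit = sm.OLS(y, X).fit()
            conf_int = fit.conf_int()
            if len(levels) > 2 and ordinal.get(name, True):
                trend = sm.OLS(y, sm.add_constant(
                    codes.codes.astype(float))).fit()
                p_conf = float(trend.pvalues[1])
                note = "linear trend p"
            elif len(levels) == 2:
                p_conf = float(fit.pvalues[1])
                note = ""
            else:
                p_conf = float(fit.f_pvalue)
                note = "joint Wald p"
            rows.append({"confounder": name, "target": target_name,
                         "level": f"{levels[0]} (reference)",
                         "n": int(ok.sum()), "estimate": 0.0,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "p": p_conf, "note": note})
            for i, lev in enumerate(levels[1:], start=1):
                rows.append({"confounder": name, "target": target_name,
                             "level": str(lev), "n": int(ok.sum()),
                             "estimate": float(fit.params[i]),
                             "ci_low": float(conf_int[i, 0]),
                             "ci_high": float(conf_int[i, 1]),
                             "p": np.nan, "note": ""})
    return pd.DataFrame(rows)
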