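"""Stage-1 screen: robust regression, ranking, multiplicity and balance."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from mrphewas import MultiplicityContext, PhenomeScreen, bonferroni_adjust, \
    confounder_balance, estimate_fdr, qq_data, rank_results
from mrphewas import test_of_proportions as proportions_test
from mrphewas.io import DataError
from mrphewas.screen import univariate_robust_screen

from conftest import make_cohort


def simple_cohort(score_len, Y):
    p = 2
    dosages = np.tile(np.array([[0.0, 1.0]]), (score_len, 1))
    dosages[0, 0] = 2.0  # non-constant
    return make_cohort(dosages, {"rs1": "A", "rs2": "C"}, Y)


class TestRobustScreenCore:
    def test_hand_fixture_matches_matrix_algebra_oracle(self):
        """6-point fixture: slope, HC1 SE and p against an explicit sandwich."""
        s = np.array([-1.0, -0.5, 0.0, 0.2, 0.8, 1.5])
        y = np.array([0.3, -0.2, 0.1, 0.5, 0.9, 1.2])
        res = univariate_robust_screen(s, y[:, None], min_complete=3)
        X = np.column_stack([np.ones(6), s])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        e = y - X @ beta
        meat = X.T @ (X * e[:, None] ** 2)
        V = np.linalg.inv(X.T @ X) @ meat @ np.linalg.inv(X.T @ X)
        se = np.sqrt(V[1, 1] * 6 / 4)  # HC1 factor n/(n-2)
        p = 2 * stats.t.sf(abs(beta[1] / se), df=4)
        assert res.gamma_hat[0] == pytest.approx(beta[1], abs=1e-10)
        assert res.robust_se[0] == pytest.approx(se, abs=1e-10)
        assert res.p_value[0] == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize("flavor", ["HC0", "HC1", "HC3"])
    def test_matches_statsmodels_with_missing(self, flavor):
        rng = np.random.default_rng(21)
        s = rng.standard_normal(80)
        Y = rng.standard_normal((80, 5))
        Y[rng.random((80, 5)) < 0.25] = np.nan
        res = univariate_robust_screen(s, Y, flavor=flavor)
        for j in range(5):
            ok = ~np.isnan(Y[:, j])
            fit = sm.OLS(Y[ok, j], sm.add_constant(s[ok])).fit(cov_type=flavor)
            assert res.gamma_hat[j] == pytest.approx(fit.params[1], abs=1e-10)
            assert res.robust_se[j] == pytest.approx(fit.bse[1], abs=1e-10)

    def test_skips_low_n_and_constant_outcomes(self):
        rng = np.random.default_rng(3)
        s = rng.standard_normal(40)
        Y = np.column_stack([rng.standard_normal(40),
                             np.full(40, 2.0),
                             np.where(np.arange(40) < 5,
                                      rng.standard_normal(40), np.nan)])
        res = univariate_robust_screen(s, Y)
        assert not np.isnan(res.p_value[0])
        assert np.isnan(res.p_value[1]) and np.isnan(res.p_value[2])
        assert res.n[2] == 5


class TestScreenEstimator:
    def test_outcome_equal_to_score_is_rank_one(self):
        rng = np.random.default_rng(17)
        s = rng.standard_normal(200)
        Y = np.column_stack([s.copy(), rng.standard_normal(200),
                             rng.standard_normal(200)])
        screen = PhenomeScreen(seed=1).fit(s, simple_cohort(200, Y))
        row = screen.results_.set_index("outcome").loc["y0"]
        assert row["p_value"] < 1e-10
        assert row["rank"] == 1

    def test_ranking_invariant_to_outcome_order(self):
        rng = np.random.default_rng(23)
        s = rng.standard_normal(150)
        Y = rng.standard_normal((150, 6)) + 0.1 * s[:, None]
        a = PhenomeScreen(seed=5).fit(s, simple_cohort(150, Y)).results_
        perm = [3, 0, 5, 1, 4, 2]
        cohort_b = simple_cohort(150, Y[:, perm])
        cohort_b.phenotypes.columns = [f"y{j}" for j in perm]
        cohort_b.outcome_meta.index = pd.Index([f"y{j}" for j in perm])
        b = PhenomeScreen(seed=5).fit(s, cohort_b).results_
        merged = a.merge(b, on="outcome", suffixes=("_a", "_b"))
        assert (merged["rank_a"] == merged["rank_b"]).all()
        np.testing.assert_allclose(merged["p_value_a"], merged["p_value_b"],
                                   atol=1e-12)

    def test_null_calibration_across_many_outcomes(self):
        """1000 independent null outcomes: ~5% reach p < 0.05."""
        rng = np.random.default_rng(29)
        n = 200
        s = rng.standard_normal(n)
        Y = rng.standard_normal((n, 1000))
        res = univariate_robust_screen(s, Y)
        frac = (res.p_value < 0.05).mean()
        band = 2.576 * np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) < band

    def test_validation_outcomes_ranked_but_not_adjusted(self):
        rng = np.random.default_rng(31)
        s = rng.standard_normal(120)
        Y = rng.standard_normal((120, 4)) + np.array([1.0, 0, 0, 0]) * s[:, None]
        cohort = make_cohort(np.tile([[1.0, 0.0]], (120, 1)) +
                             np.eye(120, 2), {"rs1": "A", "rs2": "C"}, Y,
                             validation=[True, False, False, False])
        screen = PhenomeScreen(seed=2).fit(s, cohort)
        res = screen.results_.set_index("outcome")
        assert res.loc["y0", "rank"] == 1  # validation outcome still ranked
        assert np.isnan(res.loc["y0", "p_bonferroni"])
        assert screen.multiplicity_.m == 3  # validation excluded from m
        tested = res.loc[["y1", "y2", "y3"]]
        assert (tested["p_bonferroni"] >= tested["p_value"] - 1e-15).all()


class TestRanking:
    def test_examples_and_tie_rule(self):
        df = pd.DataFrame({"outcome": ["a", "b", "c"],
                           "p_value": [0.5, 0.001, 0.05],
                           "gamma_hat": [0.1, 0.3, 0.2]})
        assert list(rank_results(df)["rank"]) == [3, 1, 2]
        tie = pd.DataFrame({"outcome": ["a", "b"], "p_value": [0.01, 0.01],
                            "gamma_hat": [0.1, 0.2]})
        assert list(rank_results(tie)["rank"]) == [2, 1]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(41)
        df = pd.DataFrame({"outcome": [f"o{i}" for i in range(50)],
                           "p_value": rng.random(50),
                           "gamma_hat": rng.standard_normal(50)})
        got = rank_results(df)
        oracle = df.sort_values("p_value").reset_index()
        for pos, idx in enumerate(oracle["index"], start=1):
            assert got.loc[idx, "rank"] == pos


class TestMultiplicity:
    @pytest.mark.parametrize("p,m,expected", [
        (0.0001, 160, 0.016), (0.01, 160, 1.0), (1 / 160, 160, 1.0)])
    def test_bonferroni(self, p, m, expected):
        assert bonferroni_adjust(p, m) == pytest.approx(expected)

    @pytest.mark.parametrize("m,alpha,k,expected", [
        (160, 0.05, 14, 0.571), (160, 0.05, 8, 1.0), (100, 0.05, 50, 0.1)])
    def test_fdr(self, m, alpha, k, expected):
        assert estimate_fdr(MultiplicityContext(m, alpha, k)) == \
            pytest.approx(expected, abs=5e-4)

    def test_fdr_no_hits_is_missing_and_monotone_in_k(self):
        assert np.isnan(estimate_fdr(MultiplicityContext(160, 0.05, 0)))
        vals = [estimate_fdr(MultiplicityContext(160, 0.05, k))
                for k in range(1, 161)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("args,expected", [
        ((14, 160, 0.05), 0.030),
        ((19, 172, (21, 172)), 0.737),
        ((8, 160, 0.05), 1.0),
    ])
    def test_proportions(self, args, expected):
        assert proportions_test(*args) == pytest.approx(expected, abs=5e-4)

    def test_proportions_errors(self):
        with pytest.raises(DataError):
            proportions_test(1, 0, 0.5)


class TestQQ:
    def test_identity_line_and_single_point(self):
        df = pd.DataFrame({"p_value": [0.25, 0.5, 0.75]})
        qq = qq_data(df)
        np.testing.assert_allclose(10 ** -qq["expected_neglog10_p"],
                                   [0.25, 0.5, 0.75])
        np.testing.assert_allclose(qq["expected_neglog10_p"],
                                   qq["observed_neglog10_p"], atol=1e-12)
        one = qq_data(pd.DataFrame({"p_value": [0.5]}))
        assert 10 ** -one["expected_neglog10_p"][0] == pytest.approx(0.5)

    def test_uniform_sample_near_line(self):
        rng = np.random.default_rng(55)
        qq = qq_data(pd.DataFrame({"p_value": rng.random(100)}))
        dev = np.abs(10 ** -qq["observed_neglog10_p"]
                     - 10 ** -qq["expected_neglog10_p"])
        assert dev.max() < 0.15

    def test_bonferroni_threshold_metadata(self):
        qq = qq_data(pd.DataFrame({"p_value": [0.1, 0.2]}), alpha=0.05)
        assert qq.attrs["bonferroni_threshold"] == pytest.approx(0.025)


class TestConfounderBalance:
    def test_independent_binary_confounder_calibrated(self):
        rng = np.random.default_rng(61)
        n, n_rep, hits = 300, 400, 0
        for _ in range(n_rep):
            s = rng.standard_normal(n)
            conf = pd.DataFrame({"c": rng.integers(0, 2, n)})
            bal = confounder_balance(s, s.copy(), conf[["c"]])
            p = bal[(bal["target"] == "score")
                    & bal["p"].notna()]["p"].iloc[0]
            hits += p < 0.05
        frac = hits / n_rep
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_exposure_split_confounder_detected_score_null(self):
        rng = np.random.default_rng(67)
        n = 2000
        s = rng.standard_normal(n)
        exposure = rng.standard_normal(n)  # independent of score
        conf = pd.DataFrame({"median_split":
                             (exposure > np.median(exposure)).astype(int)})
        bal = confounder_balance(s, exposure, conf)
        p_expo = bal[(bal["target"] == "exposure") & bal["p"].notna()]["p"].iloc[0]
        p_score = bal[(bal["target"] == "score") & bal["p"].notna()]["p"].iloc[0]
        assert p_expo < 1e-6
        assert p_score > 1e-4  # no spurious score association

    def test_single_level_skipped_and_trend_p(self):
        rng = np.random.default_rng(71)
        n = 500
        s = rng.standard_normal(n)
        levels = rng.integers(0, 4, n)
        conf = pd.DataFrame({"flat": np.zeros(n, dtype=int), "ord": levels})
        bal = confounder_balance(s + 0.2 * levels, s, conf,
                                 ordinal={"ord": True})
        flat = bal[bal["confounder"] == "flat"]
        assert (flat["note"] == "single level: skipped").all()
        ordp = bal[(bal["confounder"] == "ord") & (bal["target"] == "score")]
        assert ordp["note"].iloc[0] == "linear trend p"
        assert ordp["p"].iloc[0] < 1e-4
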