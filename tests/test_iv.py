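"""Stage-2 IV machinery: 2SLS, two-stage logistic, DWH, observational."""

import numpy as np
import pytest
import statsmodels.api as sm
from statsmodels.sandbox.regression.gmm import IV2SLS as SmIV2SLS

from mrphewas import dwh_test, first_stage, observational_estimate, \
    tsls_linear, two_stage_logistic
from mrphewas.io import DataError
from mrphewas.iv import TwoStageLeastSquares
from mrphewas.simulate import OutcomeSpec, SimConfig, simulate_cohort
from mrphewas import build_allele_score


def causal_sim(seed, n=10_000, beta=0.5, lam=0.5, delta=0.5, n_snps=32,
               weight_scale=0.05, klass="causal", **spec_kwargs):
    spec = (OutcomeSpec(name="y", klass=klass,
                        causal_beta=beta if klass == "causal" else 0.0,
                        confounder_to_outcome=lam, **spec_kwargs),)
    cfg = SimConfig(n_individuals=n, n_snps=n_snps, outcome_specs=spec,
                    seed=seed, confounder_to_exposure=delta,
                    weight_scale=weight_scale)
    cohort, w, expo, truth = simulate_cohort(cfg)
    score = build_allele_score(cohort, w)
    return cohort.phenotypes["y"].to_numpy(), expo, score, truth


class TestFirstStage:
    def test_exposure_equal_score_gives_huge_f(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(100)
        assert first_stage(s.copy(), s).F > 1e6

    def test_f_matches_matrix_oracle(self):
        rng = np.random.default_rng(2)
        s = rng.standard_normal(60)
        x = 0.3 * s + rng.standard_normal(60)
        fs = first_stage(x, s)
        X = np.column_stack([np.ones(60), s])
        beta = np.linalg.solve(X.T @ X, X.T @ x)
        e = x - X @ beta
        sigma2 = e @ e / (60 - 2)
        var_b = sigma2 * np.linalg.inv(X.T @ X)[1, 1]
        assert fs.F == pytest.approx(beta[1] ** 2 / var_b, abs=1e-8)

    def test_f_invariant_to_affine_exposure_rescaling(self):
        rng = np.random.default_rng(3)
        s = rng.standard_normal(200)
        x = 0.2 * s + rng.standard_normal(200)
        f1 = first_stage(x, s).F
        f2 = first_stage(3.5 * x - 7.0, s).F
        assert f1 == pytest.approx(f2, rel=1e-10)

    def test_f_scale_matches_two_percent_score(self):
        """A score explaining ~2% of exposure variance at n = 5,000 lands in
        the F range seen with real 32-SNP adiposity scores."""
        Fs = []
        for seed in range(5):
            _, expo, score, _ = causal_sim(seed, n=5000, weight_scale=0.044)
            Fs.append(first_stage(expo, score).F)
        assert min(Fs) > 60 and max(Fs) < 140


class TestTsls:
    def test_exact_noiseless_recovery(self):
        rng = np.random.default_rng(5)
        s = rng.standard_normal(50)
        est = tsls_linear(2.0 * s, s.copy(), s.copy())
        assert est.estimate == pytest.approx(2.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_ratio_estimator(self, seed):
        y, x, score, _ = causal_sim(seed, n=2000)
        est = tsls_linear(y, x, score)
        s = score.values
        ratio = np.cov(s, y)[0, 1] / np.cov(s, x)[0, 1]
        assert est.estimate == pytest.approx(ratio, abs=1e-10)

    def test_matches_statsmodels_iv2sls(self):
        y, x, score, _ = causal_sim(7, n=3000)
        est = tsls_linear(y, x, score)
        Z = sm.add_constant(score.values)
        X = sm.add_constant(x)
        fit = SmIV2SLS(y, X, instrument=Z).fit()
        assert est.estimate == pytest.approx(fit.params[1], abs=1e-8)

    def test_recovery_beats_confounded_ols_single_seed(self):
        y, x, score, _ = causal_sim(11)
        est = tsls_linear(y, x, score)
        obs = observational_estimate(y, x)
        se = (est.ci_high - est.ci_low) / (2 * 1.96)
        assert abs(est.estimate - 0.5) < 3 * se
        assert obs["estimate"] > 0.6  # OLS pulled upward by the confounder

    def test_ci_coverage_nominal(self):
        """95% CI covers the true effect at close-to-nominal rate."""
        cover = 0
        n_rep = 200
        for seed in range(n_rep):
            y, x, score, _ = causal_sim(seed, n=2000)
            est = tsls_linear(y, x, score)
            cover += est.ci_low <= 0.5 <= est.ci_high
        assert 0.90 <= cover / n_rep <= 0.98

    def test_reverse_causation_centered_on_null(self):
        """Outcome->exposure feedback: IV estimate near 0, OLS away from 0."""
        ivs, obss = [], []
        for seed in range(20):
            y, x, score, _ = causal_sim(seed, n=8000, klass="reverse",
                                        lam=1.0, reverse_theta=0.3)
            ivs.append(tsls_linear(y, x, score).estimate)
            obss.append(observational_estimate(y, x)["estimate"])
        assert abs(np.mean(ivs)) < 0.1
        assert np.mean(obss) > 0.2

    def test_degenerate_instrument_errors(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(100)
        s = np.zeros(100)  # constant instrument: no first-stage signal
        with pytest.raises((DataError, np.linalg.LinAlgError)):
            TwoStageLeastSquares().fit(x, rng.standard_normal(100), s)


class TestTwoStageLogistic:
    def test_null_calibration(self):
        rej = 0
        n_rep = 300
        for seed in range(n_rep):
            rng = np.random.default_rng(10_000 + seed)
            n = 1500
            s = rng.standard_normal(n)
            x = 0.2 * s + rng.standard_normal(n)
            y = (rng.random(n) < 0.5).astype(float)  # outcome independent
            est = two_stage_logistic(y, x, s)
            rej += est.p_value < 0.05
        frac = rej / n_rep
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_latent_threshold_sign_recovery(self):
        y, x, score, _ = causal_sim(13, beta=0.5, binary=True)
        est = two_stage_logistic(y, x, score)
        assert est.kind == "logistic"
        assert est.estimate > 1.0 and est.ci_low > 1.0

    def test_single_class_errors(self):
        rng = np.random.default_rng(14)
        with pytest.raises(DataError):
            two_stage_logistic(np.ones(100), rng.standard_normal(100),
                               rng.standard_normal(100))


class TestDwh:
    def test_exogenous_calibration(self):
        rej = 0
        n_rep = 200
        for seed in range(n_rep):
            y, x, score, _ = causal_sim(seed, n=10_000, lam=0.0, delta=0.0)
            rej += dwh_test(y, x, score.values) < 0.05
        assert 0.02 <= rej / n_rep <= 0.09

    def test_strong_confounding_detected(self):
        y, x, score, _ = causal_sim(42, n=10_000, lam=1.0, delta=1.0)
        assert dwh_test(y, x, score.values) < 0.01

    def test_instrumented_only_outcome_null_residual_coef(self):
        """Outcome built solely from the instrumented part of the exposure:
        the control-function residual coefficient is numerically zero."""
        rng = np.random.default_rng(15)
        n = 500
        s = rng.standard_normal(n)
        x = 0.5 * s + rng.standard_normal(n)
        fs = sm.OLS(x, sm.add_constant(s)).fit()
        y = 2.0 * np.asarray(fs.fittedvalues)
        resid = x - fs.fittedvalues
        fit = sm.OLS(y, np.column_stack([np.ones(n), x, resid])).fit()
        assert abs(fit.params[2] + fit.params[1]) < 1e-8  # residual drops out
        assert dwh_test(y, x, s) is not None

    def test_collinear_exposure_flagged(self):
        rng = np.random.default_rng(16)
        s = rng.standard_normal(100)
        assert np.isnan(dwh_test(rng.standard_normal(100), 2.0 * s + 1.0, s))


class TestObservational:
    def test_identity_outcome(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(300)
        res = observational_estimate(x.copy(), x)
        assert res["estimate"] == pytest.approx(1.0, abs=1e-10)
        assert res["p"] < 1e-30

    def test_matches_ols_oracle(self):
        rng = np.random.default_rng(18)
        x = rng.standard_normal(80)
        y = 0.4 * x + rng.standard_normal(80)
        res = observational_estimate(y, x)
        fit = sm.OLS(y, sm.add_constant(x)).fit(cov_type="HC1")
        assert res["estimate"] == pytest.approx(fit.params[1], abs=1e-10)

    def test_confounded_only_outcome_contrast(self):
        """No causal path: observational association strong, IV null."""
        ivs = []
        for seed in range(10):
            y, x, score, _ = causal_sim(seed, klass="confounded", lam=0.8)
            obs = observational_estimate(y, x)
            assert obs["p"] < 1e-10
            ivs.append(tsls_linear(y, x, score).estimate)
        assert abs(np.mean(ivs)) < 0.05  # IV estimates centered on the null
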