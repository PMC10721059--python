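"""Likelihood correctness and constrained MLE behaviour for both model families."""

import numpy as np
import pytest
import statsmodels.api as sm

from doseavg._rng import substream
from doseavg.risk_models import (
    DEFAULT_POISSON,
    DomainError,
    ModelSpec,
    _numerical_covariance,
    fit_model,
    fit_realizations,
    logistic_eor_loglik,
    null_alpha_fit,
    poisson_err_loglik,
)
from doseavg.suma import Cohort, generate_cohort, generate_poisson_outcomes, sample_mean_doses

NO_COVARIATES_LOGISTIC = ModelSpec(family="logistic_eor", confounders=())
NO_COVARIATES_POISSON = ModelSpec(family="poisson_err", confounders=())


def _cohort(y, py=None, age=40.0, gender=0.0):
    y = np.asarray(y, dtype=float)
    n = y.size
    py = np.ones(n) if py is None else np.asarray(py, dtype=float)
    return Cohort(np.full(n, age), np.full(n, gender), py, y)


class TestLogisticLoglik:
    def test_null_model_is_n_log_half(self):
        c = _cohort([1, 0, 1, 0, 1])
        ll = logistic_eor_loglik(np.array([0.0, 0.0]), np.ones(5), c, NO_COVARIATES_LOGISTIC)
        assert ll == pytest.approx(5 * np.log(0.5))

    def test_two_row_hand_computation(self):
        # odds = (1+3*1, 1+3*0) = (4, 1) -> p = (0.8, 0.5)
        c = _cohort([1, 0])
        ll = logistic_eor_loglik(np.array([0.0, 3.0]), np.array([1.0, 0.0]), c,
                                 NO_COVARIATES_LOGISTIC)
        assert ll == pytest.approx(np.log(0.8) + np.log(0.5))

    def test_boundary_raises_domain_error(self):
        c = _cohort([1, 0])
        with pytest.raises(DomainError):
            logistic_eor_loglik(np.array([0.0, -1.01]), np.array([1.0, 0.5]), c,
                                NO_COVARIATES_LOGISTIC)


class TestPoissonLoglik:
    def test_zero_counts_unit_rate(self):
        c = _cohort(np.zeros(7))
        ll = poisson_err_loglik(np.array([0.0, 0.0]), np.ones(7), c, NO_COVARIATES_POISSON)
        assert ll == pytest.approx(-7.0)

    def test_one_row_hand_computation(self):
        # Y=2, PY=1, a0=0, beta=3, D=1: ll = 2 ln 4 - 4 - ln 2
        c = _cohort([2.0])
        ll = poisson_err_loglik(np.array([0.0, 3.0]), np.array([1.0]), c, NO_COVARIATES_POISSON)
        assert ll == pytest.approx(2 * np.log(4) - 4 - np.log(2))

    def test_offset_equivariance(self):
        # scaling person-years by e^c and shifting a0 by -c leaves the rate,
        # hence the log-likelihood, unchanged
        rng = np.random.default_rng(5)
        y = rng.poisson(2.0, size=30).astype(float)
        py = rng.exponential(2.0, size=30)
        dose = rng.lognormal(-2, 0.5, size=30)
        c1 = Cohort(np.full(30, 40.0), np.zeros(30), py, y)
        c2 = Cohort(np.full(30, 40.0), np.zeros(30), py * np.e, y)
        theta1 = np.array([0.4, 2.0])
        theta2 = np.array([0.4 - 1.0, 2.0])
        ll1 = poisson_err_loglik(theta1, dose, c1, NO_COVARIATES_POISSON)
        ll2 = poisson_err_loglik(theta2, dose, c2, NO_COVARIATES_POISSON)
        assert ll2 == pytest.approx(ll1, abs=1e-9)


class TestFitModel:
    def test_null_fit_matches_standard_glm(self, small_test_data, poisson_spec):
        cohort, real, _ = small_test_data
        alpha, llf = null_alpha_fit(cohort, poisson_spec)
        theta = np.concatenate([alpha, [0.0]])
        ll = poisson_err_loglik(theta, real.true_dose(), cohort, poisson_spec)
        assert ll == pytest.approx(llf, abs=1e-6)

    def test_parameter_recovery_at_true_dose(self):
        # fitting the generating dose column recovers the true slope
        seed = 90210
        n, beta = 10_000, 3.0
        cohort = generate_cohort(n, substream(seed, "cohort"))
        dose = sample_mean_doses(n, 0.1, 2.0, substream(seed, "dose"))
        y = generate_poisson_outcomes(cohort, dose, beta, substream(seed, "y"))
        cohort = cohort.with_outcome(y)
        fit = fit_model(DEFAULT_POISSON, dose, cohort)
        assert fit.converged
        se = np.sqrt(fit.var_beta)
        assert abs(fit.beta_hat - beta) < 3 * se

    def test_aic_identity_and_row_order_invariance(self, small_test_data, poisson_spec):
        cohort, real, _ = small_test_data
        dose = real.analysis_doses()[:, 0]
        fit = fit_model(poisson_spec, dose, cohort)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik, rel=1e-15)
        perm = np.random.default_rng(3).permutation(len(cohort))
        shuffled = Cohort(cohort.age[perm], cohort.gender[perm],
                          cohort.person_years[perm], cohort.outcome[perm])
        fit2 = fit_model(poisson_spec, dose[perm], shuffled)
        assert fit2.aic == pytest.approx(fit.aic, abs=1e-5)

    def test_duplicating_rows_doubles_loglik(self, small_test_data, poisson_spec):
        cohort, real, _ = small_test_data
        dose = real.analysis_doses()[:, 1]
        fit = fit_model(poisson_spec, dose, cohort)
        doubled = Cohort(np.tile(cohort.age, 2), np.tile(cohort.gender, 2),
                         np.tile(cohort.person_years, 2), np.tile(cohort.outcome, 2))
        fit2 = fit_model(poisson_spec, np.tile(dose, 2), doubled)
        assert fit2.beta_hat == pytest.approx(fit.beta_hat, abs=1e-5)
        assert fit2.loglik == pytest.approx(2 * fit.loglik, rel=1e-9)

    def test_gradient_small_at_reported_optimum(self, small_test_data, poisson_spec):
        cohort, real, _ = small_test_data
        fit = fit_model(poisson_spec, real.analysis_doses()[:, 2], cohort)
        assert fit.converged
        h = 1e-6
        grad = np.empty(fit.n_params)
        for i in range(fit.n_params):
            e = np.zeros(fit.n_params)
            e[i] = h
            grad[i] = (
                poisson_err_loglik(fit.theta_hat + e, real.analysis_doses()[:, 2], cohort, poisson_spec)
                - poisson_err_loglik(fit.theta_hat - e, real.analysis_doses()[:, 2], cohort, poisson_spec)
            ) / (2 * h)
        assert np.max(np.abs(grad)) < 1e-3  # numerical differencing noise included

    def test_observed_information_matches_numerical_hessian(self, small_test_data, poisson_spec):
        cohort, real, _ = small_test_data
        dose = real.analysis_doses()[:, 3]
        fit = fit_model(poisson_spec, dose, cohort)
        num_cov = _numerical_covariance(poisson_spec, fit.theta_hat, dose, cohort)
        assert num_cov is not None
        assert fit.var_beta == pytest.approx(num_cov[poisson_spec.beta_index,
                                                     poisson_spec.beta_index], rel=1e-3)

    def test_all_zero_dose_flags_unidentified_slope(self, small_test_data, poisson_spec):
        cohort, _, _ = small_test_data
        fit = fit_model(poisson_spec, np.zeros(len(cohort)), cohort)
        assert fit.beta_hat == 0.0
        assert np.isinf(fit.var_beta)

    def test_logistic_family_mle_matches_glm_at_small_slope(self):
        # with beta ~ 0 the EOR model is close to plain logistic regression;
        # check the constrained optimizer against a statsmodels fit with
        # dose omitted when the true slope is zero
        rng = np.random.default_rng(8)
        n = 2000
        gender = rng.integers(0, 2, n).astype(float)
        odds = np.exp(-1.0 + 0.8 * gender)
        y = (rng.random(n) < odds / (1 + odds)).astype(float)
        c = Cohort(np.full(n, 40.0), gender, np.ones(n), y)
        dose = rng.lognormal(-2.3, 0.7, n)
        spec = ModelSpec(family="logistic_eor", confounders=("gender",))
        fit = fit_model(spec, dose, c)
        glm = sm.GLM(y, np.column_stack([np.ones(n), gender]),
                     family=sm.families.Binomial()).fit()
        assert fit.loglik >= glm.llf - 1e-6  # richer model can only fit better
        assert abs(fit.theta_hat[1] - glm.params[1]) < 0.2


class TestBatchedFits:
    def test_identical_columns_identical_results(self, small_test_data, poisson_spec):
        # identical up to SIMD-lane rounding (~1 ulp): a column's arithmetic
        # path depends on its position within the vectorized batch
        cohort, real, _ = small_test_data
        dose = real.analysis_doses()[:, 0]
        D = np.column_stack([dose, dose, dose])
        fits = fit_realizations(poisson_spec, D, cohort)
        for f in fits[1:]:
            assert f.beta_hat == pytest.approx(fits[0].beta_hat, rel=1e-13)
            assert f.loglik == pytest.approx(fits[0].loglik, rel=1e-13)
            assert np.allclose(f.theta_hat, fits[0].theta_hat, rtol=1e-13)

    def test_batch_matches_single_column_fit(self, small_test_data, poisson_spec):
        cohort, real, _ = small_test_data
        D = real.analysis_doses()[:, :6]
        fits = fit_realizations(poisson_spec, D, cohort)
        for k in (0, 3, 5):
            single = fit_model(poisson_spec, D[:, k], cohort)
            assert fits[k].beta_hat == pytest.approx(single.beta_hat, rel=1e-8)
            assert fits[k].loglik == pytest.approx(single.loglik, rel=1e-12)

    def test_worker_count_does_not_change_results(self, small_test_data, poisson_spec):
        cohort, real, _ = small_test_data
        D = real.analysis_doses()[:, :10]
        f1 = fit_realizations(poisson_spec, D, cohort, workers=1)
        f2 = fit_realizations(poisson_spec, D, cohort, workers=2)
        for a, b in zip(f1, f2):
            assert a.beta_hat == pytest.approx(b.beta_hat, rel=1e-13)
            assert a.loglik == pytest.approx(b.loglik, rel=1e-13)
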