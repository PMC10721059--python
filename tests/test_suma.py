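"""SUMA dose simulator: unit-mean errors, shared/unshared structure, cohort draws."""

import numpy as np
import pytest

from doseavg._rng import substream
from doseavg.suma import (
    SCENARIOS,
    Cohort,
    DoseRealizations,
    SumaScenario,
    generate_binary_outcomes,
    generate_cohort,
    generate_poisson_outcomes,
    generate_realizations,
    lognormal_unit_mean_params,
    poisson_rates,
    read_cohort,
    read_realizations,
    sample_mean_doses,
    write_cohort,
    write_realizations,
)


class TestLognormalUnitMean:
    def test_mu_sigma_give_unit_mean(self):
        mu, sigma = lognormal_unit_mean_params(0.223)
        assert sigma == pytest.approx(np.sqrt(0.223))
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(1.0)
        assert np.exp(sigma) == pytest.approx(1.60, abs=0.005)

    def test_zero_variance_degenerates_at_one(self):
        mu, sigma = lognormal_unit_mean_params(0.0)
        assert (mu, sigma) == (0.0, 0.0)

    def test_gsd_matches_direct_arithmetic(self):
        _, sigma = lognormal_unit_mean_params(0.632)
        assert np.exp(sigma) == pytest.approx(2.21, abs=0.005)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            lognormal_unit_mean_params(-0.1)

    @pytest.mark.parametrize(
        "name,gsd_sm,gsd_um",
        [
            ("scenario1", 1.8, 1.6),
            ("scenario2", 2.2, 1.6),
            ("scenario3", 2.2, 2.0),
            ("scenario4", 2.7, 1.6),
        ],
    )
    def test_scenario_presets_round_to_tabulated_gsds(self, name, gsd_sm, gsd_um):
        sc = SCENARIOS[name]
        assert round(sc.gsd_shared, 1) == gsd_sm
        assert round(sc.gsd_unshared, 1) == gsd_um

    def test_sample_mean_of_unit_mean_draws(self, rng):
        for var in (0.223, 0.954):
            mu, sigma = lognormal_unit_mean_params(var)
            draws = rng.lognormal(mu, sigma, size=1_000_000)
            assert abs(draws.mean() - 1.0) < 0.005


class TestSampleMeanDoses:
    def test_degenerate_gsd_one(self, rng):
        Z = sample_mean_doses(10, 0.1, 1.0, rng)
        assert np.allclose(Z, 0.1)

    def test_sample_median_matches(self, rng):
        Z = sample_mean_doses(100_000, 0.1, 2.0, rng)
        assert abs(np.median(Z) / 0.1 - 1) < 0.02
        assert np.all(Z > 0)

    def test_empty_cohort_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_mean_doses(0, 0.1, 2.0, rng)
        with pytest.raises(ValueError):
            sample_mean_doses(10, -0.1, 2.0, rng)


class TestGenerateRealizations:
    def test_no_error_limit_reproduces_baseline(self, rng):
        Z = sample_mean_doses(20, 0.1, 2.0, rng)
        real = generate_realizations(Z, SumaScenario(0, 0), K=5, rng=rng)
        assert np.allclose(real.doses, Z[:, None])

    def test_shared_only_columns_are_scalar_multiples(self, rng):
        Z = sample_mean_doses(50, 0.1, 2.0, rng)
        real = generate_realizations(Z, SumaScenario(0.3, 0.0), K=8, rng=rng)
        ratios = real.doses / Z[:, None]
        assert np.allclose(ratios, ratios[0, :][None, :])
        # shared draws differ across columns
        assert len(np.unique(np.round(ratios[0], 12))) == 8

    def test_column_means_converge_to_baseline(self, rng):
        Z = sample_mean_doses(200, 0.1, 2.0, rng)
        real = generate_realizations(Z, "scenario1", K=5000, rng=rng)
        med = np.argsort(Z)[len(Z) // 2]
        rel_dev = abs(real.doses[med].mean() / Z[med] - 1)
        assert rel_dev < 0.03

    def test_true_column_excluded_from_analysis(self, rng):
        Z = sample_mean_doses(10, 0.1, 2.0, rng)
        real = generate_realizations(Z, "scenario1", K=6, rng=rng).with_true_index(2)
        X = real.analysis_doses()
        assert X.shape == (10, 5)
        for k in range(5):
            assert not np.array_equal(X[:, k], real.true_dose())
        # analysis matrix is a copy, not a view into the stored doses
        X[0, 0] = -1
        assert real.doses[0, 0] != -1

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValueError):
            generate_realizations(np.array([0.1]), "scenario1", 0, rng)
        with pytest.raises(ValueError):
            generate_realizations(np.array([0.1]), "nonexistent", 5, rng)


class TestGenerateCohort:
    def test_distributional_moments(self, rng):
        c = generate_cohort(100_000, rng)
        assert abs(c.age.mean() - 35.0) < 0.2
        assert abs(c.gender.mean() - 0.5) < 0.01
        assert abs(c.person_years.mean() / 2.0 - 1) < 0.02

    def test_single_row(self, rng):
        c = generate_cohort(1, rng)
        assert len(c) == 1 and 20 <= c.age[0] <= 50 and c.person_years[0] > 0

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_cohort(0, rng)


class TestPoissonOutcomes:
    def test_null_slope_rate_closed_form(self, rng):
        c = Cohort(age=np.array([40.0]), gender=np.array([0.0]), person_years=np.array([1.0]))
        lam = poisson_rates(c, np.array([5.0]), beta=0.0)
        assert lam[0] == pytest.approx(np.e)

    def test_rate_plugin_arithmetic(self):
        c = Cohort(age=np.array([40.0]), gender=np.array([1.0]), person_years=np.array([1.0]))
        lam = poisson_rates(c, np.array([1.0]), beta=3.0)
        assert lam[0] == pytest.approx(np.exp(2.5) * 4)

    def test_empirical_mean_matches_rate(self, rng):
        n = 100_000
        c = Cohort(age=np.full(n, 30.0), gender=np.ones(n), person_years=np.full(n, 2.0))
        dose = np.full(n, 0.5)
        y = generate_poisson_outcomes(c, dose, 3.0, rng)
        lam = poisson_rates(c, dose, 3.0)[0]
        assert abs((y / 2.0).mean() / lam - 1) < 0.01

    def test_negative_excess_rejected(self, rng):
        c = Cohort(age=np.array([40.0]), gender=np.array([0.0]), person_years=np.array([1.0]))
        with pytest.raises(ValueError):
            generate_poisson_outcomes(c, np.array([1.0]), beta=-1.5, rng=rng)


class TestBinaryOutcomes:
    def test_unit_odds_gives_half_probability(self, rng):
        n = 200_000
        c = Cohort(age=np.full(n, 30.0), gender=np.zeros(n), person_years=np.ones(n))
        y = generate_binary_outcomes(c, np.zeros(n), (0.0, 0.0, 0.0, 0.0), rng)
        assert abs(y.mean() - 0.5) < 0.005

    def test_odds_four_gives_p08(self, rng):
        n = 200_000
        c = Cohort(age=np.full(n, 30.0), gender=np.zeros(n), person_years=np.ones(n))
        y = generate_binary_outcomes(c, np.ones(n), (0.0, 0.0, 3.0, 0.0), rng)
        assert abs(y.mean() - 0.8) < 0.005

    def test_nonpositive_odds_rejected(self, rng):
        c = Cohort(age=np.array([30.0]), gender=np.array([0.0]), person_years=np.array([1.0]))
        with pytest.raises(ValueError):
            generate_binary_outcomes(c, np.array([1.0]), (0.0, 0.0, -2.0, 0.0), rng)


class TestRoundtrip:
    def test_cohort_and_realization_files(self, tmp_path, rng):
        c = generate_cohort(25, rng).with_outcome(np.arange(25.0))
        Z = sample_mean_doses(25, 0.1, 2.0, rng)
        real = generate_realizations(Z, "scenario2", 7, rng)
        write_cohort(c, tmp_path / "cohort.csv")
        write_realizations(real, tmp_path / "doses.tsv")
        c2 = read_cohort(tmp_path / "cohort.csv")
        real2 = read_realizations(tmp_path / "doses.tsv")
        assert np.allclose(c2.age, c.age) and np.allclose(c2.outcome, c.outcome)
        assert np.allclose(real2.doses, real.doses)

    def test_scenario_invariants(self):
        with pytest.raises(ValueError):
            SumaScenario(-0.1, 0.2)
        with pytest.raises(ValueError):
            DoseRealizations(np.zeros((3, 4)), true_index=4)
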