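import numpy as np
import pytest

from doseavg._rng import substream
from doseavg.risk_models import DEFAULT_POISSON
from doseavg.suma import (
    generate_cohort,
    generate_poisson_outcomes,
    generate_realizations,
    sample_mean_doses,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_test_data():
    """One small simulated test: cohort with outcomes + a realization set.

    Scenario-1 errors, N=300, K=40, true slope 3; the true column is excluded
    from analysis.  Shared across tests that just need realistic inputs.
    """
    seed = 424242
    n, k, beta = 300, 40, 3.0
    cohort = generate_cohort(n, substream(seed, "cohort"))
    Z = sample_mean_doses(n, 0.1, 2.0, substream(seed, "baseline"))
    real = generate_realizations(Z, "scenario1", k, substream(seed, "realizations"))
    real = real.with_true_index(0)
    y = generate_poisson_outcomes(cohort, real.true_dose(), beta, substream(seed, "outcomes"))
    return cohort.with_outcome(y), real, beta


@pytest.fixture(scope="session")
def poisson_spec():
    return DEFAULT_POISSON
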