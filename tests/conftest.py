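import warnings

import pytest

from telodyn import SimTruth, simulate_study, summarize_samples

# mixed-model boundary/convergence warnings are expected on simulated data
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def default_study():
    return simulate_study(SimTruth(seed=42))


@pytest.fixture(scope="session")
def default_samples(default_study):
    return summarize_samples(default_study.measurements)


@pytest.fixture(scope="session")
def small_study():
    """A reduced study (6 cohorts x 10 birds) for model-fitting tests."""
    return simulate_study(SimTruth(seed=7, n_cohorts=6, birds_per_cohort=10))


@pytest.fixture(scope="session")
def small_samples(small_study):
    return summarize_samples(small_study.measurements)
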