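import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from facemimic.design import GroundTruthParams, SessionDesign
from facemimic.preprocess import PreprocParams
from facemimic.responses import response_pairs
from facemimic.synthetic import simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: Reduced-rate recording used across tests to keep filtering cheap; the
#: preprocessing cutoffs are scaled to match via PreprocParams.for_rate.
FAST_RATE = 500.0


@pytest.fixture(scope="session")
def fast_preproc():
    return PreprocParams.for_rate(FAST_RATE)


@pytest.fixture(scope="session")
def small_design():
    return SessionDesign(n_subjects=4, trials_per_condition=2, emg_rate_hz=FAST_RATE)


@pytest.fixture(scope="session")
def stats_design():
    return SessionDesign(n_subjects=10, trials_per_condition=4, emg_rate_hz=FAST_RATE)


@pytest.fixture(scope="session")
def default_params():
    return GroundTruthParams(seed=1234)


@pytest.fixture(scope="session")
def stats_cohort(stats_design, default_params):
    return simulate_cohort(stats_design, default_params, seed=42)


@pytest.fixture(scope="session")
def stats_pairs(stats_cohort, fast_preproc):
    return response_pairs(stats_cohort, preproc=fast_preproc)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
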