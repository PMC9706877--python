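import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tbitriage import default_config, simulate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def study_config():
    """Default simulation config emulating the published cohort."""
    return default_config()


@pytest.fixture(scope="session")
def cohort65(study_config):
    """One simulated 65-patient cohort (30 moderate-severe + 35 unrecorded)."""
    return simulate_cohort(study_config, seed=11)


@pytest.fixture(scope="session")
def ms_cohort(cohort65):
    return [r for r in cohort65 if r.subcohort == "moderate_severe"]


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
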