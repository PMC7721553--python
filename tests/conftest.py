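import pytest
from hypothesis import HealthCheck, settings

from artbia import netherlands_2016, run_scenarios
from artbia.cohort_model import baseline_volumes

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def nl():
    """The shipped Netherlands 2016 fixture."""
    return netherlands_2016()


@pytest.fixture(scope="session")
def nl_baseline(nl):
    return baseline_volumes(nl.population, nl.mix)


@pytest.fixture(scope="session")
def nl_results(nl):
    """Scenario propagation of the fixture in printed-benefit mode."""
    return run_scenarios(nl)
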