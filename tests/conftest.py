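import pytest
from hypothesis import HealthCheck, settings

from vnaflow.core import AnalytePanel, MethodConstants, default_layout
from vnaflow.simulate import SimConfig

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    return AnalytePanel.default()


@pytest.fixture(scope="session")
def constants():
    return MethodConstants()


@pytest.fixture
def sim():
    return SimConfig(seed=7)


@pytest.fixture
def noiseless_sim():
    return SimConfig(seed=7).noiseless()


@pytest.fixture
def layout():
    return default_layout("BTEST")
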