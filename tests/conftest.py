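import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from reservesim.io_cli import MULLET, SEABASS, medes_config
from reservesim.scenario import run_simulation

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mullet():
    return MULLET


@pytest.fixture(scope="session")
def seabass():
    return SEABASS


@pytest.fixture(scope="session")
def medes_result():
    """Full Medes run (100 + 100 years, fixed 3.5 fee)."""
    return run_simulation(medes_config())


@pytest.fixture(scope="session")
def medes_capped_result():
    """Medes run with the year-8 dive cap at the fixed 3.5 fee."""
    return run_simulation(medes_config(cap_dives=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
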