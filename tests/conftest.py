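import warnings

import pytest
from hypothesis import HealthCheck, settings

from ifxsim import ModelParams, UnitConventions
from ifxsim.presets import CD_INIT, UC_INIT

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    """Shared literature parameter set (clearance 3.5e-6 1/s)."""
    return ModelParams()


@pytest.fixture(scope="session")
def cd_init():
    return CD_INIT


@pytest.fixture(scope="session")
def uc_init():
    return UC_INIT


@pytest.fixture(scope="session")
def conv():
    return UnitConventions()


@pytest.fixture(autouse=True)
def _silence_clearance_window_warning():
    """Sweeps and Hill updates legitimately step outside the literature window."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="antibody clearance")
        yield
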