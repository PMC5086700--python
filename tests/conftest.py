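import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from uvbody.body import make_voxel_human
from uvbody.engine import make_angular_grid
from uvbody.scenarios import ScenarioPair, run_scenario_pair, sza_sweep
from uvbody.spectral import SpectralGrid


@pytest.fixture(scope="session")
def spectral_grid():
    return SpectralGrid.default()


@pytest.fixture(scope="session")
def angular_grid():
    return make_angular_grid()


@pytest.fixture(scope="session")
def human_body():
    return make_voxel_human()


@pytest.fixture(scope="session")
def rural_table():
    """Default valley/mountain battery (rural valley aerosol)."""
    return run_scenario_pair()


@pytest.fixture(scope="session")
def urban_table():
    """Battery with the urban-valley variant (mountain stays rural)."""
    return run_scenario_pair(ScenarioPair.default(valley_aerosol="urban"))


@pytest.fixture(scope="session")
def sweep_table():
    """Solar-zenith sweep 45-89 deg at mountain albedo 0.6."""
    return sza_sweep()
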