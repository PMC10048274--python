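import numpy as np
import pytest

from mirprofile.accuracy_profile import LevelData
from mirprofile.simulate import SimConfig, simulate_calibration_set
from mirprofile.preprocess import mask_water_regions


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def quiet_cfg() -> SimConfig:
    """Noise-free, nuisance-free configuration for exactness tests."""
    return SimConfig(seed=0, sigma_noise=0.0, sigma_day=0.0, nuisance_on=False)


@pytest.fixture(scope="session")
def cal_masked(default_cfg):
    """Default masked calibration set (105 spectra), shared across tests."""
    return mask_water_regions(simulate_calibration_set(default_cfg))


@pytest.fixture()
def toy_level() -> LevelData:
    """3 days x 3 replicates around 50 with day-to-day drift."""
    return LevelData(
        y_r=50.0,
        measurements=np.array([[48.0, 50.0, 52.0], [47.0, 49.0, 51.0], [50.0, 52.0, 54.0]]),
    )
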