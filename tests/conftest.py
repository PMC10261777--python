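import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def time_grid():
    """Soaking times of the study design: every 5 min up to 60 min."""
    return np.arange(0, 61, 5.0)


@pytest.fixture
def peleg_curve(time_grid):
    """Noise-free curve from the published control/55 °C Peleg constants."""
    from rehydkin import PelegParams, RehydrationCurve, peleg_moisture

    params = PelegParams(8.13, 0.146)
    x = peleg_moisture(time_grid, 0.10, params)
    return RehydrationCurve("control", 55.0, time_grid, x, 0.10), params
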