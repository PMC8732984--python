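import numpy as np
import pytest

from shakeflask.kinetics import CultureState, SamplingSchedule
from shakeflask.radiative import FlaskGeometry, LightSetting


@pytest.fixture
def geometry():
    return FlaskGeometry(V=0.2, h=0.04)


@pytest.fixture
def daily_grid():
    return np.arange(0.0, 241.0, 24.0)


@pytest.fixture
def daily_schedule(daily_grid):
    return SamplingSchedule(sample_times=tuple(daily_grid[1:]), V_sample=0.0075, c_N_feed=1.0)


@pytest.fixture
def standard_initial():
    return CultureState(X=0.1, V=0.2, c_N=1.0)


@pytest.fixture
def setting_536():
    return LightSetting(I_S=536.0, L=12.0)
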