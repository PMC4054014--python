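import numpy as np
import pytest

from oriband.conditions import scaled_condition
from oriband.stimulus import FilterSpec, make_fourier_grid


@pytest.fixture(scope="session")
def small_grid():
    """64x64 grid at 16 px/deg: Nyquist 8 cy/deg, resolution 0.25 cy/deg."""
    return make_fourier_grid(64, 16.0)


@pytest.fixture(scope="session")
def study_filter():
    """The 1-octave, 5 cy/deg signal filter at 16 deg orientation bandwidth."""
    return FilterSpec(center_sf=5.0, sf_bandwidth=1.0, ori_bandwidth_2sided=16.0)


@pytest.fixture(scope="session")
def cond128():
    """Reduced-grid 90-deg-bandwidth study condition used by heavier tests."""
    return scaled_condition(90.0, size=128)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
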