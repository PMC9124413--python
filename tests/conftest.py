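import numpy as np
import pytest

from aerodist.granulometry import DropletDistribution
from aerodist.imaging_io import VoxelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def reference_dist():
    """The nebulizer's reported aerosol: x50,3 = 2.59 um, sigma_g = 1.73."""
    return DropletDistribution(x50_3=2.59, gsd=1.73)


@pytest.fixture
def lds_edges():
    """Log-spaced diameter grid spanning the instrument's 0.5-175 um range."""
    return np.geomspace(0.5, 175.0, 41)


@pytest.fixture
def small_volume(rng):
    """A 12-slice random non-negative volume for windowing tests."""
    return VoxelVolume(data=rng.gamma(2.0, 1.0, size=(12, 6, 6)))


def tve_prefix_oracle(values, percent):
    """Independent exhaustive reference for the top-voxel count.

    Sorts descending and walks every prefix until the running sum first
    STRICTLY exceeds percent% of the total. Pure-Python, no shortcuts.
    """
    ordered = sorted((float(v) for v in values), reverse=True)
    total = sum(ordered)
    threshold = percent / 100.0 * total
    running = 0.0
    for k, v in enumerate(ordered, start=1):
        running += v
        if running > threshold:
            return k
    return len(ordered)
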