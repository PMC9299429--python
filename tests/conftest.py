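import numpy as np
import pytest

from mousect import ScanGeometry, Volume, desk_geometry


@pytest.fixture
def tiny_geometry() -> ScanGeometry:
    """Small odd-dimension detector: the central pixel ray passes the isocenter."""
    return desk_geometry(n_angles=8, detector_cols=25, detector_rows=21,
                         pixel_pitch_mm=2.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_volume(shape=(16, 16, 16), voxel=1.0, values=None) -> Volume:
    vol = Volume.zeros(shape, voxel)
    if values is not None:
        vol.values[:] = values
    return vol
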