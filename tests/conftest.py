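import numpy as np
import pytest

import froidose as fd


@pytest.fixture(scope="session")
def mats():
    return fd.predefined()


@pytest.fixture(scope="session")
def spec90():
    from froidose.instruments import carm_spectrum

    return carm_spectrum(90.0)


def _water_cube(mats, n=16, voxel_mm=6.0):
    labels = np.ones((n, n, n), dtype=np.int16)
    half = n * voxel_mm / 2.0
    return fd.VoxelPhantom(
        labels,
        (voxel_mm,) * 3,
        (-half, -half, -half),
        {0: ("air", mats["air"]), 1: ("water", mats["water"])},
        {0: mats["air"].density, 1: 1.0},
    )


@pytest.fixture(scope="session")
def water_cube(mats):
    return _water_cube(mats)


@pytest.fixture(scope="session")
def head5(mats):
    """Coarse synthetic head for fast simulation tests."""
    return fd.make_synthetic_head(5.0, seed=1)


@pytest.fixture(scope="session")
def head4(mats):
    return fd.make_synthetic_head(4.0, seed=1)
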