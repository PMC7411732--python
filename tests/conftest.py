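import numpy as np
import pytest
from hypothesis import settings

import palsim as ps

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def array() -> ps.TransducerArray:
    return ps.L14_5_38


@pytest.fixture(scope="session")
def water_volume() -> ps.VoxelVolume:
    """Small non-scattering, non-absorbing volume for forward-model tests.

    40 x 50 x 10 mm at 0.25 mm voxels, transducer face at y = 0.
    """
    labels = np.zeros((160, 200, 40), dtype=np.int32)
    mat = {0: ps.OpticalProperties(mu_a=0.0, mu_s=0.0, g=0.0, eta=1.37)}
    return ps.VoxelVolume(labels, 0.25, mat, origin=(-20.0, 0.0, -5.0))


@pytest.fixture(scope="session")
def point_image_setup(array, water_volume):
    """Reusable grid + duration for point-target reconstruction tests."""
    from palsim.experiments import safe_rf_duration

    grid = ps.ImageGrid.for_array(array, 32.0, dx=0.1, standoff=19.5)
    duration = safe_rf_duration(water_volume, array)
    return grid, duration
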