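import numpy as np
import pytest

from eatkit.synthetic import PhantomSpec, generate_phantom_pair
from eatkit.volume import CTVolume, Phase, VoxelMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A fast, small phantom: ~4k fat voxels, 40 mm axial extent."""
    return PhantomSpec(
        shape=(48, 48, 40),
        spacing=(1.0, 1.0, 1.0),
        inner_radii_mm=(10.0, 10.0, 10.0),
        outer_radii_mm=(15.0, 15.0, 15.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return generate_phantom_pair(small_phantom_spec)


def make_volume(hu, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                phase=Phase.CONTRAST, tube_voltage=120.0):
    return CTVolume(np.asarray(hu, dtype=float), spacing, origin,
                    tube_voltage=tube_voltage, phase=phase)


def full_mask(volume):
    return VoxelMask(np.ones(volume.shape, dtype=bool), volume.spacing, volume.origin)
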