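import numpy as np
import pytest

from legmuscle.core_io import FatWaterVolume, LabelMap, VoxelGeometry
from legmuscle.phantom import PhantomSpec, make_leg_phantom


@pytest.fixture
def unit_geometry():
    return VoxelGeometry(affine=np.eye(4), dims=(6, 6, 4))


@pytest.fixture
def dixon_geometry():
    return VoxelGeometry(affine=np.diag([0.71, 0.71, 5.0, 1.0]), dims=(96, 64, 10))


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Default noiseless two-leg phantom and its exact truth labels."""
    return make_leg_phantom(PhantomSpec(noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_phantom():
    return make_leg_phantom(PhantomSpec(noise_sd=2.0, seed=7))


def make_volume(fat, water, voxel=(1.0, 1.0, 1.0)):
    fat = np.asarray(fat, dtype=float)
    geom = VoxelGeometry(affine=np.diag([*voxel, 1.0]), dims=fat.shape)
    return FatWaterVolume(fat=fat, water=np.asarray(water, dtype=float),
                          geometry=geom)


def make_labels(arr, voxel=(1.0, 1.0, 1.0)):
    arr = np.asarray(arr)
    geom = VoxelGeometry(affine=np.diag([*voxel, 1.0]), dims=arr.shape)
    return LabelMap(labels=arr, geometry=geom)
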