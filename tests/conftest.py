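import numpy as np
import pytest

from ctradiomics.grids import ImageVolume, MaskVolume
from ctradiomics.phantom import PhantomParams, PhantomSampler, generate_phantom


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    """ImageVolume from a nested list/array (z, y, x)."""
    return ImageVolume(voxels=np.asarray(values, dtype=float), spacing=spacing)


def make_mask(values, spacing=(1.0, 1.0, 1.0)):
    return MaskVolume(voxels=np.asarray(values, dtype=np.uint8), spacing=spacing)


def full_mask_like(arr, spacing=(1.0, 1.0, 1.0)):
    return MaskVolume(voxels=np.ones(np.shape(arr), dtype=np.uint8), spacing=spacing)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic textured phantom (28^3 grid, ~1600-voxel VOI)."""
    params = PhantomParams(
        shape=(28, 28, 28), semi_axes_mm=(9.0, 7.5, 6.5), sigma2=150.0, gamma=0.3
    )
    return generate_phantom(params, seed=11)


@pytest.fixture(scope="session")
def small_sampler():
    """Phantom distribution used by fast cohort-level tests."""
    return PhantomSampler(
        base=PhantomParams(shape=(28, 28, 28), semi_axes_mm=(9.0, 7.5, 6.5))
    )


def random_voi_levels(rng, max_side=6, n_levels=5):
    """Random discretized VOI: levels 1..Ng inside a random mask, 0 outside."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[rng.integers(0, mask.size)] = True
    levels[~mask] = 0
    return levels
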