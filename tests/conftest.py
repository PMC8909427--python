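import numpy as np
import pytest

from segstress.synthetic import PhantomParams, make_phantom
from segstress.volumes_io import BinaryMask


@pytest.fixture(scope="session")
def ball_phantom():
    """Radius-10 mm textured ball on a 48^3 1 mm grid (image, mask)."""
    return make_phantom(PhantomParams(seed=7))


@pytest.fixture(scope="session")
def ball_mask(ball_phantom):
    return ball_phantom[1]


def random_small_mask(rng: np.random.Generator, max_side: int = 8) -> BinaryMask:
    """Random non-empty mask on a small unit-spacing grid."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    vox = rng.random(shape) < rng.uniform(0.2, 0.8)
    if not vox.any():
        vox[tuple(rng.integers(0, s) for s in shape)] = True
    return BinaryMask(voxels=vox, spacing=(1.0, 1.0, 1.0))


def random_small_levels(rng: np.random.Generator, max_levels: int = 3) -> np.ndarray:
    """Random level grid <= 4x4x2 with 0 marking out-of-ROI voxels."""
    shape = (int(rng.integers(2, 5)), int(rng.integers(2, 5)), int(rng.integers(1, 3)))
    levels = rng.integers(1, max_levels + 1, size=shape)
    roi = rng.random(shape) < 0.8
    if not roi.any():
        roi[0, 0, 0] = True
    return np.where(roi, levels, 0).astype(np.int32)
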