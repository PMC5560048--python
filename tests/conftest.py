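import numpy as np
import pytest

from jointquant import ImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_stack(voxels, voxel_size=(1.0, 1.0, 1.0), channels=None, origin=(0.0, 0.0, 0.0)):
    """Build an ImageStack from a (z, c, y, x) array with defaults filled in."""
    voxels = np.asarray(voxels)
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(voxels.shape[1]))
    return ImageStack(voxels=voxels, voxel_size=voxel_size, channel_names=channels, origin=origin)


@pytest.fixture
def stack_factory():
    return make_stack
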