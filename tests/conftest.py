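import numpy as np
import pytest

from pcscale import phantom

# a grid small enough for brute-force voxel-loop oracles but large enough to
# host all nine structures
SMALL_GRID = (16, 64, 64)
SMALL_SPACING = (5.0, 2.0, 2.0)


@pytest.fixture(scope="session")
def small_atlas():
    return phantom.build_atlas(SMALL_GRID, SMALL_SPACING)


@pytest.fixture(scope="session")
def small_labels(small_atlas):
    return small_atlas.label_volume()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
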