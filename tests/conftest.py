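import numpy as np
import pytest

from wmfc import make_atlas
from wmfc.preprocess import Volume4D


@pytest.fixture(scope="session")
def small_atlas():
    """Reduced 8-bundle x 10-region atlas used across module tests."""
    return make_atlas((14, 14, 9), 8, 10, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def random_volume(rng):
    return Volume4D(rng.standard_normal((6, 5, 4, 40)), tr_seconds=2.0,
                    voxel_size_mm=2.0)
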