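import numpy as np
import pytest

from bmmap import GridSpec, build_toy_atlas


@pytest.fixture(scope="session")
def toy_atlas():
    """Default 18-region toy atlas (8 lateral pairs + 2 midline)."""
    return build_toy_atlas()


@pytest.fixture(scope="session")
def small_atlas():
    """Smaller atlas for fast cohort simulations."""
    return build_toy_atlas(shape=(16, 18, 16), n_lateral_pairs=3, n_midline=1,
                           infratentorial_fraction=0.3)


@pytest.fixture
def grid10():
    return GridSpec(shape=(10, 10, 10), voxel_volume=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
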