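import numpy as np
import pytest

from mesomap.atlas import make_test_atlas
from mesomap.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def test_atlas():
    """Bundled mirrored test atlas at 256 px."""
    atlas, ccs, defs = make_test_atlas(size=256)
    return atlas, ccs, defs


@pytest.fixture(scope="session")
def clean_scene():
    """Noiseless, vessel-free canonical phantom (128 px)."""
    return make_phantom(PhantomSpec(image_size=(128, 128), vessel_count=0, noise_sigma=0.0))


@pytest.fixture(scope="session")
def small_scene():
    """Small canonical phantom for movie simulations (64 px)."""
    return make_phantom(PhantomSpec(image_size=(64, 64), vessel_count=0, noise_sigma=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
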