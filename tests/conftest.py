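import numpy as np
import pytest

from macgan import PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One small phantom (image, labels) shared across read-only tests."""
    cfg = PhantomConfig(shape=(16, 32, 32), liver_axes=(5.0, 9.0, 9.0),
                        n_tumors=1, tumor_radius_range=(1.5, 2.5), seed=3)
    return make_phantom(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(8, 8, 8), p=0.3):
    return rng.random(shape) < p
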