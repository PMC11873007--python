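import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ramp2d():
    """4x4 single-channel ramp with distinct values 0..15."""
    from lazyresample import make_meta_image

    return make_meta_image(np.arange(16, dtype=np.float32).reshape(1, 4, 4))


@pytest.fixture
def random_volume(rng):
    from lazyresample import make_meta_image

    return make_meta_image(rng.random((1, 12, 12, 12)).astype(np.float32))
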