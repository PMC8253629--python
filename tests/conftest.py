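import numpy as np
import pytest

from elastoqc import Image, PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    """32x32 random image in [0, 1]."""
    return Image(rng.random((32, 32)))


@pytest.fixture
def default_bundle():
    """The default 256x256 lesion phantom (background 0.4, contrast 2, L=4)."""
    return make_phantom(PhantomSpec(seed=7))


@pytest.fixture
def small_spec():
    """A small phantom for fast filter/pipeline tests."""
    return PhantomSpec(
        height=96,
        width=96,
        lesion_center=(48, 34),
        lesion_radius=16.0,
        seed=3,
    )
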