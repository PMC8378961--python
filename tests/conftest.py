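import numpy as np
import pytest

from mcrn.data import ImageGray, PhantomParams, generate_phantom, phantom_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    return ImageGray(rng.uniform(size=(32, 32)))


@pytest.fixture
def clean_phantom():
    return generate_phantom(
        PhantomParams(seed=3, size=64, texture_amplitude=0.0, noise_sigma=0.0)
    )


@pytest.fixture(scope="session")
def small_corpus():
    return phantom_corpus(6, 48, seed=99)
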