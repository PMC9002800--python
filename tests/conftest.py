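import numpy as np
import pytest

from quintex.encoder import encode_image
from quintex.synthdata import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def phantom():
    """One mid-density phantom image + mask (64 px, deterministic)."""
    image, mask, label, woman = make_phantom(PhantomSpec(3, size=64, seed=11))
    return image, mask


@pytest.fixture(scope="session")
def encoded_phantom(phantom):
    """The phantom encoded with the default three-scale riu4 configuration."""
    image, mask = phantom
    return encode_image(image, mask)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
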