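import numpy as np
import pytest

from idman import ImagePair, PhantomSpec, generate_phantom, make_pair
from idman.model import IDMAN, TINY_CONFIG


@pytest.fixture(scope="session")
def tiny_model() -> IDMAN:
    """A fixed-seed tiny network shared by read-only forward-pass tests."""
    return IDMAN(TINY_CONFIG, rng=0)


@pytest.fixture(scope="session")
def phantom_pairs() -> list[ImagePair]:
    """Eight deterministic 64x64 phantom pairs at scale 2."""
    return [
        make_pair(generate_phantom(PhantomSpec(size=64, n_ellipses=3, seed=s)), 2)
        for s in range(8)
    ]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
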