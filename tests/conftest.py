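import numpy as np
import pytest

from omdetect import get_family


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


FAMILY_CASES = [
    ("gaussian", 1),
    ("gaussian", 3),
    ("gamma", 1),
    ("bernoulli", 1),
    ("bernoulli", 4),
]


@pytest.fixture(params=FAMILY_CASES, ids=[f"{n}-d{d}" for n, d in FAMILY_CASES])
def family(request):
    name, d = request.param
    return get_family(name, d)


def random_natural(family, rng, scale=1.0):
    """A random interior point of the family's natural domain."""
    if family.name == "gamma":
        return -np.exp(rng.normal(scale=scale, size=1))
    return rng.normal(scale=scale, size=family.d)
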