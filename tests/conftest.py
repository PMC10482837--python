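import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import limbalign as la

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_case():
    """One canonical noise-free phantom at package defaults."""
    return la.generate_phantom(la.PhantomSpec())


@pytest.fixture(scope="session")
def normal_cases():
    """A small bank of noise-free normal-population phantoms."""
    return [la.generate_phantom(la.sample_spec(4000 + i, "normal"))
            for i in range(8)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_blob_mask(rng, shape=(48, 48)):
    """A random non-empty mask built from a few rectangles and a disc."""
    m = np.zeros(shape, dtype=bool)
    for _ in range(rng.integers(1, 4)):
        r0 = int(rng.integers(0, shape[0] - 4))
        c0 = int(rng.integers(0, shape[1] - 4))
        h = int(rng.integers(2, 12))
        w = int(rng.integers(2, 12))
        m[r0:min(r0 + h, shape[0]), c0:min(c0 + w, shape[1])] = True
    cr, cc = rng.integers(5, shape[0] - 5), rng.integers(5, shape[1] - 5)
    rad = int(rng.integers(2, 7))
    R, C = np.ogrid[:shape[0], :shape[1]]
    m |= (R - cr) ** 2 + (C - cc) ** 2 <= rad ** 2
    return m
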