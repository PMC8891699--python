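import numpy as np
import pytest

from hippounet.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def sham_phantom():
    return generate_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def tbi_phantom():
    spec = PhantomSpec(
        injury="TBI",
        timepoint_days=30,
        lesion_severity=0.6,
        atrophy_fraction=0.25,
        ventricle_enlargement=0.3,
        seed=5,
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape, p=0.3):
    """Random nonempty boolean mask."""
    while True:
        m = rng.random(shape) < p
        if m.any():
            return m
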