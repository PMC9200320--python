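import numpy as np
import pytest

from flexidock.fixtures import ToyComplexSpec, make_helix, make_toy_complex


@pytest.fixture(scope="session")
def helix12():
    return make_helix(12)


@pytest.fixture(scope="session")
def toy_complex():
    """(unbound receptor, unbound ligand, bound pose) with a 20 deg loop backrub."""
    return make_toy_complex(ToyComplexSpec(backrub_angle=20.0))


@pytest.fixture(scope="session")
def bound_pose(toy_complex):
    return toy_complex[2]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rigid(rng_like):
    """A random proper rigid transform for invariance tests."""
    from flexidock.geom import RigidTransform, random_rotation

    R = random_rotation(rng_like)
    t = rng_like.normal(0, 10.0, size=3)
    return RigidTransform(R, t)
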