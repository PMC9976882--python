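import numpy as np
import pytest

from dnabind.fixtures import clamp_fixture, clamp_unbound_system, make_cg_backend


@pytest.fixture(scope="session")
def clamp():
    return clamp_fixture()


@pytest.fixture(scope="session")
def unbound_system():
    system, collections, fx = clamp_unbound_system(seed=11)
    return system, collections, fx


@pytest.fixture(scope="session")
def cg_backend(unbound_system):
    system, _, _ = unbound_system
    return make_cg_backend(system)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
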