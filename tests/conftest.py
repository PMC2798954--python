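import numpy as np
import pytest

from metapersist import LocalMapSpec, build_topology, make_rng


@pytest.fixture
def logistic4():
    return LocalMapSpec("logistic", N=300, lam=4.0)


@pytest.fixture
def ricker50():
    return LocalMapSpec("ricker", N=200, r=float(np.log(50.0)))


@pytest.fixture
def nb_spec():
    return LocalMapSpec("nicholson_bailey", N=500, lam=2.0, a=1.0, c=1)


@pytest.fixture
def two_patch():
    return build_topology("two_patch")


@pytest.fixture
def ring4():
    return build_topology("chain_1d", 4)


@pytest.fixture
def single_patch():
    return build_topology("chain_1d", 1)


@pytest.fixture
def rng():
    return make_rng(1234)
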