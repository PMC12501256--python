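import numpy as np
import pytest

from thermopix import CodingScheme, twin_prime_smatrix


@pytest.fixture(scope="session")
def S15():
    return twin_prime_smatrix(3, 5)


@pytest.fixture(scope="session")
def S35():
    return twin_prime_smatrix(5, 7)


@pytest.fixture(scope="session")
def S143():
    return twin_prime_smatrix(11, 13)


@pytest.fixture(scope="session")
def scheme91():
    """The bench configuration: order 143, 91-pattern compressed scan."""
    return CodingScheme(p=11, q=13, m=91)


@pytest.fixture(scope="session")
def scheme_full():
    return CodingScheme(p=11, q=13, m=143)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
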