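import numpy as np
import pytest

from shefl.crypto_ring import FixedPointCodec, Modulus


@pytest.fixture(scope="session")
def q17():
    return Modulus(Q=17, bit_length=5, max_parties=3)


@pytest.fixture(scope="session")
def q31():
    return Modulus(Q=31, bit_length=5, max_parties=3)


@pytest.fixture(scope="session")
def q97():
    return Modulus(Q=97, bit_length=7, max_parties=3)


@pytest.fixture(scope="session")
def q10007():
    return Modulus(Q=10007, bit_length=14, max_parties=4)


@pytest.fixture(scope="session")
def codec_p3(q10007):
    return FixedPointCodec(precision=3, modulus=q10007)


@pytest.fixture(scope="session")
def default_codec_p13():
    from shefl.crypto_ring import default_codec

    return default_codec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
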