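import numpy as np
import pytest

from shortmer.alphabet import CombinatorialAlphabet, default_omega
from shortmer.codec import EncodingParams


@pytest.fixture(scope="session")
def omega():
    return default_omega()


@pytest.fixture(scope="session")
def alphabet16_5(omega):
    return CombinatorialAlphabet.binomial(omega, 5)


@pytest.fixture(scope="session")
def alphabet16_3(omega):
    return CombinatorialAlphabet.binomial(omega, 3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_params(alphabet16_5):
    """A miniature system (short payloads, small blocks) for fast channel tests."""
    return EncodingParams(alphabet=alphabet16_5, payload_len=8, block_size=4,
                          rs_payload=(8, 12), rs_block=(4, 6))


def random_bits(rng, n: int) -> str:
    return "".join("1" if b else "0" for b in rng.integers(0, 2, n))
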