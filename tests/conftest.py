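"""Shared fixtures: codes, brute-force decode oracle, synthetic instances."""

from itertools import product

import pytest
from hypothesis import settings

from phcmap import build_phc, dna_to_word, hamming

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def code5():
    return build_phc(5)


@pytest.fixture(scope="session")
def code21():
    return build_phc(21)


@pytest.fixture(scope="session")
def all5():
    """All 1024 length-5 words."""
    return list(product(range(4), repeat=5))


@pytest.fixture(scope="session")
def codewords5(code5, all5):
    return [w for w in all5 if code5.is_code_word(w)]


@pytest.fixture(scope="session")
def bf_decode5(codewords5):
    """Independent decode oracle: the unique code word within distance 1,
    found by exhaustive search over the 64 code words (no syndromes)."""
    def _decode(w):
        near = [c for c in codewords5 if hamming(c, w) <= 1]
        assert len(near) == 1
        return near[0]
    return _decode


def word(s: str):
    return dna_to_word(s)
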