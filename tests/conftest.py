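import numpy as np
import pytest

from phenoxscreen.library import SubstitutionPattern, build_library


@pytest.fixture(scope="session")
def library():
    return build_library()


@pytest.fixture(scope="session")
def all_raw_tuples():
    """All 3125 raw slot tuples over the substituent alphabet."""
    from itertools import product

    from phenoxscreen.library import SUBSTITUENT_CODES

    return [SubstitutionPattern(t) for t in product(SUBSTITUENT_CODES, repeat=5)]


@pytest.fixture
def all_h_pattern():
    return SubstitutionPattern(("H", "H", "H", "H", "H"))


@pytest.fixture
def bht_pattern():
    """Butylated hydroxytoluene radical: tBu at both ortho positions, Me para."""
    return SubstitutionPattern(("tBu", "H", "Me", "H", "tBu"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
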