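import numpy as np
import pytest

from hapseg import HaplotypeMatrix, MISSING


def mat_from_strings(rows):
    """Build a matrix from '0'/'1'/'?' strings (test helper)."""
    code = {"0": 0, "1": 1, "?": MISSING}
    return HaplotypeMatrix(np.array([[code[c] for c in r] for r in rows], dtype=np.int8))


@pytest.fixture
def strings_matrix():
    return mat_from_strings


@pytest.fixture
def all_identical():
    return mat_from_strings(["0110"] * 4)


@pytest.fixture
def all_distinct():
    return mat_from_strings(["000", "011", "101", "110"])
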