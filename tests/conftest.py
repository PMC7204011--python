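import numpy as np
import pytest

from dotprint import ProteinSequence, load_substitution_matrix
from dotprint.alphabet import AMINO_ACIDS


@pytest.fixture(scope="session")
def blosum62():
    return load_substitution_matrix("BLOSUM62")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)


def random_sequence(rng: np.random.Generator, length: int, id: str = "rand") -> ProteinSequence:
    return ProteinSequence(id, "".join(rng.choice(list(AMINO_ACIDS), size=length)))


@pytest.fixture(scope="session")
def tandem_exact():
    """Exact tandem repeat: a fixed 25-residue unit, 4 copies, no flanks."""
    unit = "MKTAYIAKQRQISFVKSHFSRQLEE"
    assert len(unit) == 25
    return ProteinSequence("tandem4x25", unit * 4)
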