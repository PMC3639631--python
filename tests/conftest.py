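import numpy as np
import pytest

from fractalseq.seq_io import NucleotideSequence

BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, n, id="rand"):
    return NucleotideSequence(id=id, residues="".join(BASES[i] for i in rng.integers(0, 4, n)))


@pytest.fixture
def random_sequence_factory():
    return random_sequence
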