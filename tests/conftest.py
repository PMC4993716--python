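import numpy as np
import pytest

from vrflp.digestion import default_enzymes
from vrflp.seqio import AlignedSet, SequenceRecord
from vrflp.synthetic_data import table2_fixture


@pytest.fixture(scope="session")
def enzymes():
    return default_enzymes()


@pytest.fixture(scope="session")
def enzyme_map(enzymes):
    return {e.name: e for e in enzymes}


@pytest.fixture(scope="session")
def table2():
    return table2_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(20160823)


def make_alignment(sequences, prefix="s"):
    return AlignedSet(
        tuple(
            SequenceRecord(id=f"{prefix}{i + 1}", residues=seq)
            for i, seq in enumerate(sequences)
        )
    )


@pytest.fixture
def alignment_factory():
    return make_alignment


def random_acgt(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def acgt_factory():
    return random_acgt
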