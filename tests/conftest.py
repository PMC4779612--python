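import numpy as np
import pytest

from orthosift.io_formats import SequenceRecord, SpeciesTable

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, length=200):
    return "".join(rng.choice(list(AA), size=length))


def make_records(seqs_by_species):
    """{'sp1': ['SEQ', ...], ...} -> list of SequenceRecord with ids sp1g1..."""
    records = []
    for sp in sorted(seqs_by_species):
        for i, s in enumerate(seqs_by_species[sp], 1):
            records.append(SequenceRecord(seq_id=f"{sp}g{i}", species=sp, protein=s))
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_group_table():
    return SpeciesTable({"sp1": "A", "sp2": "A", "sp3": "B", "sp4": "B"})
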