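import numpy as np
import pytest

from cladedelim import SimScenario, distance_matrix, simulate_clade_dataset
from cladedelim.seqio import Alignment, SequenceRecord


def make_alignment(seqs, ids=None, **meta_per_record):
    """Build an Alignment from raw sequence strings.

    ``meta_per_record`` values are lists parallel to ``seqs`` (e.g.
    country=['PK', 'EG', ...]).
    """
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    records = []
    for i, (sid, seq) in enumerate(zip(ids, seqs)):
        kwargs = {key: vals[i] for key, vals in meta_per_record.items()}
        records.append(SequenceRecord(id=sid, sequence=seq, **kwargs))
    return Alignment(records)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-scenario simulated dataset (5 clades x 20 sequences)."""
    return simulate_clade_dataset(SimScenario(seed=11))


@pytest.fixture(scope="session")
def default_dm(default_dataset):
    return distance_matrix(default_dataset.alignment)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
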