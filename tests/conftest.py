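import numpy as np
import pytest

from mhcview.data_io import AMINO_ACIDS, ProteinRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length):
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length))


@pytest.fixture
def random_records(rng):
    """50 labelled records with lengths on both sides of the window boundary."""
    records = []
    for i in range(50):
        length = int(rng.choice([30, 200, 1000, 1022, 1500]))
        records.append(
            ProteinRecord(f"r{i:03d}", random_sequence(rng, length), int(i % 2))
        )
    return records
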