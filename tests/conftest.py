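import numpy as np
import pytest

from rnafam import LabeledDataset, SequenceRecord

ALPHABET = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length):
    return "".join(rng.choice(list(ALPHABET), size=length))


@pytest.fixture
def random_sequences(rng):
    def make(n, min_len=20, max_len=200):
        return [random_sequence(rng, int(rng.integers(min_len, max_len + 1))) for _ in range(n)]

    return make


@pytest.fixture
def toy_dataset():
    """Tiny labeled dataset: two classes of mutually dissimilar sequences."""
    rng = np.random.default_rng(7)
    records = []
    for label in ("famA", "famB"):
        for i in range(10):
            seq = "".join(rng.choice(list(ALPHABET), size=40))
            records.append(SequenceRecord(f"{label}_{i}", seq, label))
    return LabeledDataset(records)
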