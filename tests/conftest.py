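import numpy as np
import pytest

from hinttok.mutation import STANDARD_AA, Mutation, MutantRecord
from hinttok.splitting import LabeledDataset


def random_record(rng: np.random.Generator, record_id: str, length: int = 40,
                  max_mutations: int = 4, label: str = "x") -> MutantRecord:
    letters = list(STANDARD_AA)
    wt = "".join(letters[i] for i in rng.integers(len(letters), size=length))
    k = int(rng.integers(0, max_mutations + 1))
    positions = rng.choice(length, size=k, replace=False) + 1
    muts = []
    for p in sorted(int(x) for x in positions):
        ref = wt[p - 1]
        alts = [a for a in letters if a != ref]
        muts.append(Mutation(p, ref, alts[int(rng.integers(len(alts)))]))
    return MutantRecord(record_id, wt, tuple(muts), label)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_labeled_dataset():
    """60 variants of one wild type, two imbalanced classes, 1-3 mutations."""
    rng = np.random.default_rng(7)
    letters = list(STANDARD_AA)
    wt = "".join(letters[i] for i in rng.integers(len(letters), size=50))
    records = []
    for i in range(60):
        k = int(rng.integers(1, 4))
        positions = rng.choice(50, size=k, replace=False) + 1
        muts = []
        for p in sorted(int(x) for x in positions):
            ref = wt[p - 1]
            alts = [a for a in letters if a != ref]
            muts.append(Mutation(p, ref, alts[int(rng.integers(len(alts)))]))
        label = "LOF" if rng.random() < 0.3 else "WT_like"
        records.append(MutantRecord(f"r{i:03d}", wt, tuple(muts), label))
    return LabeledDataset.from_records(records)
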