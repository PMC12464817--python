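"""Train/validation/test partitioning protocols for mutational libraries.

Two strategies are provided.  *Multi-label stratification* builds joint
strata over (class label, mutation-count bin) and samples each stratum
proportionally, preserving both the label distribution and the
mutation-count distribution across sets.  *Position-grouped* splitting
forces every variant mutating a given residue position into the same
set — positions co-occurring in one record are merged transitively — so
the held-out sets test generalization to unseen positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mutation import MutantRecord

#: Mutation-count bins used for joint stratification.
MUTATION_COUNT_BINS = ("1", "2", "3-5", "6+")


class SplitError(ValueError):
    """Invalid split specification or an unsatisfiable constraint."""


def mutation_count_bin(n: int) -> str:
    if n <= 1:
        return "1"
    if n == 2:
        return "2"
    if n <= 5:
        return "3-5"
    return "6+"


@dataclass(frozen=True)
class LabeledDataset:
    """Records plus the ordered set of class labels."""

    records: tuple[MutantRecord, ...]
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise SplitError("need at least 2 records")
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise SplitError("record ids must be unique")
        missing = {r.label for r in self.records} - set(self.classes)
        if missing:
            raise SplitError(f"labels not in class set: {sorted(missing)}")

    @classmethod
    def from_records(cls, records: Sequence[MutantRecord]) -> "LabeledDataset":
        classes = tuple(sorted({r.label for r in records}))
        return cls(tuple(records), classes)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class SplitSpec:
    """Ratios, strategy and seed for one partition."""

    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    strategy: str = "multilabel_stratified"
    seed: int = 0
    tolerance: float = 0.05

    def __post_init__(self) -> None:
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise SplitError(f"ratios must be 3 positive fractions, got {self.ratios}")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise SplitError(f"ratios must sum to 1, got {sum(self.ratios)}")
        if self.strategy not in ("multilabel_stratified", "position_grouped"):
            raise SplitError(f"unknown strategy {self.strategy!r}")


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/val/test index lists with an audit of proportions."""

    train: tuple[int, ...]
    val: tuple[int, ...]
    test: tuple[int, ...]
    spec: SplitSpec
    audit: dict = field(default_factory=dict, compare=False)

    @property
    def sets(self) -> dict[str, tuple[int, ...]]:
        return {"train": self.train, "val": self.val, "test": self.test}


def _floor_targets(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    """val/test sizes floored; the remainder goes to train."""
    n_val = int(np.floor(ratios[1] * n))
    n_test = int(np.floor(ratios[2] * n))
    return n - n_val - n_test, n_val, n_test


def multilabel_stratified_split(ds: LabeledDataset, spec: SplitSpec) -> DatasetSplit:
    """Joint (label, mutation-count-bin) stratified three-way split.

    Each stratum is shuffled with the spec seed and sliced at floored
    targets (remainders to train).  Strata with fewer members than the
    three sets go wholly to train with a warning.
    """
    if spec.strategy != "multilabel_stratified":
        raise SplitError("spec.strategy must be 'multilabel_stratified'")
    rng = np.random.default_rng(spec.seed)
    strata: dict[tuple[str, str], list[int]] = {}
    for i, rec in enumerate(ds.records):
        key = (rec.label, mutation_count_bin(len(rec.mutations)))
        strata.setdefault(key, []).append(i)
    train: list[int] = []
    val: list[int] = []
    test: list[int] = []
    for key in sorted(strata):
        idx = np.array(strata[key])
        if len(idx) < 3:
            warnings.warn(
                f"stratum {key} has {len(idx)} record(s) (< 3 sets); assigned to train",
                stacklevel=2,
            )
            train.extend(idx.tolist())
            continue
        rng.shuffle(idx)
        n_train, n_val, n_test = _floor_targets(len(idx), spec.ratios)
        train.extend(idx[:n_train].tolist())
        val.extend(idx[n_train : n_train + n_val].tolist())
        test.extend(idx[n_train + n_val :].tolist())
    split = DatasetSplit(tuple(sorted(train)), tuple(sorted(val)), tuple(sorted(test)), spec)
    return DatasetSplit(split.train, split.val, split.test, spec, validate_split(ds, split))


def position_groups(ds: LabeledDataset) -> list[list[int]]:
    """Connected components of records linked by shared mutation positions.

    Positions co-occurring within one record are merged transitively, so a
    record at {5, 80} and another at {80, 200} fall into one group.
    Records with no mutations each form their own singleton group.
    """
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        parent[find(a)] = find(b)

    pos_root: dict[int, int] = {}  # position -> representative record index
    for i, rec in enumerate(ds.records):
        for p in rec.positions:
            if p in pos_root:
                union(i, pos_root[p])
            else:
                pos_root[p] = i
    groups: dict[int, list[int]] = {}
    for i in range(len(ds.records)):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def position_grouped_split(ds: LabeledDataset, spec: SplitSpec) -> DatasetSplit:
    """Split whole position groups so no position recurs across sets.

    Groups are assigned largest-first (seed-shuffled among equal sizes) to
    the set with the largest remaining deficit, breaking ties toward the
    set whose label distribution the group best rebalances.
    """
    if spec.strategy != "position_grouped":
        raise SplitError("spec.strategy must be 'position_grouped'")
    rng = np.random.default_rng(spec.seed)
    groups = position_groups(ds)
    if len(groups) == 1:
        raise SplitError("a single position group covers every record; cannot split")
    order = rng.permutation(len(groups))
    groups = [groups[i] for i in order]
    groups.sort(key=len, reverse=True)  # stable: seed order kept among equals

    n = len(ds.records)
    targets = _floor_targets(n, spec.ratios)
    names = ("train", "val", "test")
    assigned: dict[str, list[int]] = {k: [] for k in names}
    class_counts: dict[str, dict[str, int]] = {k: {c: 0 for c in ds.classes} for k in names}
    global_frac = {
        c: sum(1 for r in ds.records if r.label == c) / n for c in ds.classes
    }

    for grp in groups:
        deficits = [targets[j] - len(assigned[k]) for j, k in enumerate(names)]
        best = max(deficits)
        tied = [k for j, k in enumerate(names) if deficits[j] == best]
        if len(tied) > 1:
            # Label-balance tiebreak: minimise post-assignment divergence
            # from the global class fractions.
            def divergence(k: str) -> float:
                total = len(assigned[k]) + len(grp)
                div = 0.0
                for c in ds.classes:
                    cnt = class_counts[k][c] + sum(
                        1 for i in grp if ds.records[i].label == c
                    )
                    div += abs(cnt / total - global_frac[c])
                return div

            tied.sort(key=lambda k: (divergence(k), names.index(k)))
        chosen = tied[0]
        assigned[chosen].extend(grp)
        for i in grp:
            class_counts[chosen][ds.records[i].label] += 1

    split = DatasetSplit(
        tuple(sorted(assigned["train"])),
        tuple(sorted(assigned["val"])),
        tuple(sorted(assigned["test"])),
        spec,
    )
    return DatasetSplit(split.train, split.val, split.test, spec, validate_split(ds, split))


def validate_split(ds: LabeledDataset, split: DatasetSplit) -> dict:
    """Audit partition validity, per-class proportions and position overlap.

    Under position grouping the overlap count must be zero; violations are
    flagged in the report rather than raised.
    """
    n = len(ds.records)
    all_idx = [i for part in (split.train, split.val, split.test) for i in part]
    if any(i < 0 or i >= n for i in all_idx):
        raise SplitError("split contains out-of-range indices")
    partition_valid = sorted(all_idx) == list(range(n))

    report: dict = {
        "n_records": n,
        "partition_valid": partition_valid,
        "sizes": {k: len(v) for k, v in split.sets.items()},
        "class_counts": {},
        "class_fractions": {},
    }
    for name, idx in split.sets.items():
        counts = {c: 0 for c in ds.classes}
        for i in idx:
            counts[ds.records[i].label] += 1
        report["class_counts"][name] = counts
        report["class_fractions"][name] = {
            c: (counts[c] / len(idx) if idx else 0.0) for c in ds.classes
        }

    pos_sets = {
        name: set().union(*(ds.records[i].positions for i in idx), set())
        for name, idx in split.sets.items()
    }
    overlap = (
        len(pos_sets["train"] & pos_sets["val"])
        + len(pos_sets["train"] & pos_sets["test"])
        + len(pos_sets["val"] & pos_sets["test"])
    )
    report["position_overlap"] = overlap
    report["position_disjoint"] = overlap == 0
    return report


def split_dataset(ds: LabeledDataset, spec: SplitSpec) -> DatasetSplit:
    """Dispatch on ``spec.strategy``."""
    if spec.strategy == "multilabel_stratified":
        return multilabel_stratified_split(ds, spec)
    return position_grouped_split(ds, spec)
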