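"""Partition validity, stratification quality and position disjointness."""

import numpy as np
import pytest

from hinttok.mutation import Mutation, MutantRecord
from hinttok.splitting import (
    DatasetSplit,
    LabeledDataset,
    SplitError,
    SplitSpec,
    multilabel_stratified_split,
    mutation_count_bin,
    position_grouped_split,
    position_groups,
    validate_split,
)
from .conftest import random_record


def _single_mutant(i, wt, pos, label):
    ref = wt[pos - 1]
    alt = "A" if ref != "A" else "C"
    return MutantRecord(f"m{i}", wt, (Mutation(pos, ref, alt),), label)


@pytest.fixture(scope="module")
def balanced_100():
    """100 single-mutant records, two classes 50/50, unique positions."""
    rng = np.random.default_rng(3)
    letters = "ACDEFGHIKLMNPQRSTVWY"
    wt = "".join(letters[i] for i in rng.integers(20, size=120))
    recs = [
        _single_mutant(i, wt, i + 1, "pos" if i % 2 == 0 else "neg")
        for i in range(100)
    ]
    return LabeledDataset.from_records(recs)


class TestSpecValidation:
    def test_ratios_must_sum_to_one(self):
        with pytest.raises(SplitError):
            SplitSpec((0.5, 0.5, 0.2))

    def test_ratios_must_be_positive(self):
        with pytest.raises(SplitError):
            SplitSpec((1.0, -0.1, 0.1))

    def test_unknown_strategy(self):
        with pytest.raises(SplitError):
            SplitSpec((0.8, 0.1, 0.1), strategy="leave_one_out")


class TestMutationCountBins:
    @pytest.mark.parametrize(
        "n,bin_", [(1, "1"), (2, "2"), (3, "3-5"), (5, "3-5"), (6, "6+"), (40, "6+")]
    )
    def test_bins(self, n, bin_):
        assert mutation_count_bin(n) == bin_


class TestStratifiedSplit:
    def test_balanced_sizes_and_proportions(self, balanced_100):
        spec = SplitSpec((0.8, 0.1, 0.1), "multilabel_stratified", seed=0)
        split = multilabel_stratified_split(balanced_100, spec)
        assert split.audit["sizes"] == {"train": 80, "val": 10, "test": 10}
        for name in ("train", "val", "test"):
            frac = split.audit["class_fractions"][name]["pos"]
            assert abs(frac - 0.5) <= spec.tolerance

    def test_single_class_sizes(self):
        rng = np.random.default_rng(5)
        recs = [random_record(rng, f"s{i}", label="only") for i in range(50)]
        ds = LabeledDataset.from_records(recs)
        split = multilabel_stratified_split(
            ds, SplitSpec((0.8, 0.1, 0.1), "multilabel_stratified", 1)
        )
        # per-stratum floors with remainders to train
        sizes = split.audit["sizes"]
        assert sizes["val"] <= 5 + 4 and sizes["test"] <= 5 + 4
        assert sum(sizes.values()) == 50

    def test_tiny_stratum_falls_back_to_train(self, balanced_100):
        recs = list(balanced_100.records) + [
            MutantRecord(
                "rare", balanced_100.records[0].wt_sequence,
                tuple(
                    Mutation(p, balanced_100.records[0].wt_sequence[p - 1], "A"
                             if balanced_100.records[0].wt_sequence[p - 1] != "A" else "C")
                    for p in (101, 103, 105, 107, 109, 111)
                ),
                "pos",
            )
        ]
        ds = LabeledDataset.from_records(recs)
        spec = SplitSpec((0.8, 0.1, 0.1), "multilabel_stratified", 0)
        with pytest.warns(UserWarning, match="assigned to train"):
            split = multilabel_stratified_split(ds, spec)
        assert ds.records.index(recs[-1]) in split.train

    def test_partition_property_many_seeds(self, balanced_100):
        for seed in range(30):
            spec = SplitSpec((0.72, 0.13, 0.15), "multilabel_stratified", seed)
            split = multilabel_stratified_split(balanced_100, spec)
            assert split.audit["partition_valid"]
            assert not (set(split.train) & set(split.val))
            assert not (set(split.train) & set(split.test))
            assert not (set(split.val) & set(split.test))

    def test_determinism(self, balanced_100):
        spec = SplitSpec((0.8, 0.1, 0.1), "multilabel_stratified", 42)
        a = multilabel_stratified_split(balanced_100, spec)
        b = multilabel_stratified_split(balanced_100, spec)
        assert (a.train, a.val, a.test) == (b.train, b.val, b.test)


class TestPositionGroups:
    def test_transitive_closure(self):
        wt = "ACDEFGHIKLMNPQRSTVWY" * 10

        def rec(rid, positions):
            muts = []
            for p in positions:
                ref = wt[p - 1]
                muts.append(Mutation(p, ref, "A" if ref != "A" else "C"))
            return MutantRecord(rid, wt, tuple(muts), "x")

        ds = LabeledDataset.from_records(
            [rec("a", [5, 80]), rec("b", [80, 200]), rec("c", [7])]
        )
        groups = {frozenset(g) for g in position_groups(ds)}
        assert frozenset({0, 1}) in groups
        assert frozenset({2}) in groups

    def test_union_find_oracle_randomized(self, rng):
        """Connected components must match a brute-force transitive closure
        over the record co-occurrence graph."""
        for trial in range(40):
            recs = [random_record(rng, f"g{trial}_{i}", length=15) for i in range(12)]
            # ensure uniqueness of ids and at least 2 records
            ds = LabeledDataset.from_records(recs)
            groups = {frozenset(g) for g in position_groups(ds)}

            # oracle: repeated pairwise merging until fixpoint
            merged = [set(r.positions) | {("rec", i)} for i, r in enumerate(recs)]
            changed = True
            while changed:
                changed = False
                for i in range(len(merged)):
                    for j in range(i + 1, len(merged)):
                        if merged[i] and merged[j] and (
                            {p for p in merged[i] if not isinstance(p, tuple)}
                            & {p for p in merged[j] if not isinstance(p, tuple)}
                        ):
                            merged[i] |= merged[j]
                            merged[j] = set()
                            changed = True
            oracle = {
                frozenset(x[1] for x in comp if isinstance(x, tuple))
                for comp in merged
                if comp
            }
            assert groups == oracle


class TestPositionGroupedSplit:
    def test_unique_positions_behave_like_stratified(self, balanced_100):
        spec = SplitSpec((0.8, 0.1, 0.1), "position_grouped", 0)
        split = position_grouped_split(balanced_100, spec)
        sizes = split.audit["sizes"]
        assert abs(sizes["train"] - 80) <= 2
        assert split.audit["position_disjoint"]

    def test_shared_position_forced_together(self):
        wt = "ACDEFGHIKLMNPQRSTVWY"
        recs = [
            MutantRecord(f"r{i}", wt, (Mutation(10, wt[9], a),), "x")
            for i, a in enumerate("AC")
        ] + [MutantRecord("r2", wt, (Mutation(3, wt[2], "A"),), "x")]
        ds = LabeledDataset.from_records(recs)
        for seed in range(20):
            split = position_grouped_split(
                ds, SplitSpec((0.4, 0.3, 0.3), "position_grouped", seed)
            )
            for part in split.sets.values():
                assert {0, 1} <= set(part) or not ({0, 1} & set(part))

    def test_single_group_errors(self):
        wt = "ACDEFGHIKLMNPQRSTVWY"
        recs = [
            MutantRecord(f"r{i}", wt, (Mutation(5, wt[4], a),), "x")
            for i, a in enumerate("ACD")
        ]
        ds = LabeledDataset.from_records(recs)
        with pytest.raises(SplitError, match="single position group"):
            position_grouped_split(ds, SplitSpec((0.8, 0.1, 0.1), "position_grouped", 0))

    def test_position_disjointness_brute_force_100_seeds(self, rng):
        """Across 100+ seeded splits of random multi-mutant libraries the
        three sets never share a mutated position."""
        recs = [random_record(rng, f"p{i}", length=30, max_mutations=3) for i in range(80)]
        ds = LabeledDataset.from_records(recs)
        for seed in range(100):
            split = position_grouped_split(
                ds, SplitSpec((0.8, 0.1, 0.1), "position_grouped", seed)
            )
            pos = {
                name: set().union(*(ds.records[i].positions for i in idx), set())
                for name, idx in split.sets.items()
            }
            assert not (pos["train"] & pos["val"])
            assert not (pos["train"] & pos["test"])
            assert not (pos["val"] & pos["test"])
            assert split.audit["partition_valid"]

    def test_determinism(self, balanced_100):
        spec = SplitSpec((0.8, 0.1, 0.1), "position_grouped", 9)
        a = position_grouped_split(balanced_100, spec)
        b = position_grouped_split(balanced_100, spec)
        assert (a.train, a.val, a.test) == (b.train, b.val, b.test)


class TestValidateSplit:
    def test_corrupted_split_flagged(self, balanced_100):
        spec = SplitSpec((0.8, 0.1, 0.1), "position_grouped", 0)
        split = position_grouped_split(balanced_100, spec)
        # move one train record into val as a duplicate position violation
        bad = DatasetSplit(split.train, split.val + (split.train[0],), split.test, spec)
        audit = validate_split(balanced_100, bad)
        assert not audit["partition_valid"]

    def test_shared_position_counted(self):
        wt = "ACDEFGHIKLMNPQRSTVWY"
        recs = [
            MutantRecord(f"r{i}", wt, (Mutation(10, wt[9], a),), "x")
            for i, a in enumerate("ACDE")
        ]
        ds = LabeledDataset.from_records(recs)
        spec = SplitSpec((0.5, 0.25, 0.25), "position_grouped", 0)
        bad = DatasetSplit((0, 1), (2,), (3,), spec)
        audit = validate_split(ds, bad)
        assert audit["position_overlap"] >= 1
        assert not audit["position_disjoint"]

    def test_out_of_range_raises(self, balanced_100):
        spec = SplitSpec((0.8, 0.1, 0.1), "multilabel_stratified", 0)
        bad = DatasetSplit((0, 1, 999), (2,), (3,), spec)
        with pytest.raises(SplitError, match="out-of-range"):
            validate_split(balanced_100, bad)
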