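"""Cross-validation split contracts for the four extrapolation regimes."""

import itertools

import numpy as np
import pytest

from reactionfunnel.datasplit import SplitAssignment, make_split
from reactionfunnel.errors import SplitError
from reactionfunnel.surf import ReactionDataset

from conftest import make_record

ARENES = ["c1ccncc1", "c1cnc(C)nc1", "c1ccc2ncccc2c1", "c1cc(F)ncc1",
          "c1cc(Cl)ncc1", "c1cnc(N)nc1"]
ACIDS = ["CC(=O)O", "CCC(=O)O", "CC(C)C(=O)O", "OC(=O)C1CC1",
         "OC(=O)C1CCC1", "OC(=O)C1CCCC1"]


def grid_dataset(n_arenes=6, n_acids=6):
    records = []
    for i, (a, b) in enumerate(itertools.product(ARENES[:n_arenes], ACIDS[:n_acids])):
        records.append(make_record(i, arene=a, acid=b))
    return ReactionDataset(records)


def fold_maps(dataset):
    arene_of = {r.reaction_id: r.arene for r in dataset.records}
    acid_of = {r.reaction_id: r.acid for r in dataset.records}
    return arene_of, acid_of


class TestDefinitionalContracts:
    def test_1da_each_acid_in_exactly_one_test_fold(self):
        ds = grid_dataset()
        split = make_split(ds, "1DA", k=3, seed=0)
        _, acid_of = fold_maps(ds)
        seen = []
        for fold in split.folds:
            train_set, val_set, test_set = map(set, (fold.train, fold.val, fold.test))
            assert not (train_set & test_set) and not (val_set & test_set)
            assert not (train_set & val_set)
            test_acids = {acid_of[i] for i in fold.test}
            train_acids = {acid_of[i] for i in fold.train} | {acid_of[i] for i in fold.val}
            assert not (test_acids & train_acids)
            seen.append(test_acids)
        # each acid held out exactly once
        all_held = list(itertools.chain.from_iterable(seen))
        assert sorted(all_held) == sorted(set(acid_of.values()))

    def test_2d_test_entities_absent_from_train(self):
        ds = grid_dataset()
        split = make_split(ds, "2D", k=3, seed=0)
        arene_of, acid_of = fold_maps(ds)
        for fold in split.folds:
            test_arenes = {arene_of[i] for i in fold.test}
            test_acids = {acid_of[i] for i in fold.test}
            for i in fold.train + fold.val:
                assert arene_of[i] not in test_arenes
                assert acid_of[i] not in test_acids

    def test_2d_k2_quarter_test_half_dropped(self):
        """On a fully crossed 6x6 grid with equal 2-way partitions, the 2D
        intersection keeps 1/4 of the cells as test and drops 1/2, matching
        brute-force enumeration of the 36 cells."""
        ds = grid_dataset()
        split = make_split(ds, "2D", k=2, seed=0)
        n = len(ds)
        for fold in split.folds:
            assert len(fold.test) == n // 4
            used = len(fold.train) + len(fold.val) + len(fold.test)
            assert n - used == n // 2  # dropped cells

    def test_0d_test_sets_partition_records(self):
        ds = grid_dataset()
        split = make_split(ds, "0D", k=4, seed=3)
        all_test = list(itertools.chain.from_iterable(f.test for f in split.folds))
        assert sorted(all_test) == sorted(r.reaction_id for r in ds.records)


class TestPropertyOverRandomGrids:
    def test_invariants_hold_for_random_toy_datasets(self, rng):
        for trial in range(50):
            n_ar = int(rng.integers(4, 7))
            n_ac = int(rng.integers(4, 7))
            k = int(rng.integers(2, 4))
            ds = grid_dataset(n_ar, n_ac)
            mode = ["0D", "1DN", "1DA", "2D"][trial % 4]
            split = make_split(ds, mode, k=k, seed=int(rng.integers(10000)))
            arene_of, acid_of = fold_maps(ds)
            covered = []
            for fold in split.folds:
                s = set(fold.train) | set(fold.val) | set(fold.test)
                assert len(s) == len(fold.train) + len(fold.val) + len(fold.test)
                if mode == "1DN":
                    assert not ({arene_of[i] for i in fold.test}
                                & {arene_of[i] for i in fold.train + fold.val})
                if mode == "1DA":
                    assert not ({acid_of[i] for i in fold.test}
                                & {acid_of[i] for i in fold.train + fold.val})
                if mode == "2D":
                    assert not ({arene_of[i] for i in fold.test}
                                & {arene_of[i] for i in fold.train + fold.val})
                    assert not ({acid_of[i] for i in fold.test}
                                & {acid_of[i] for i in fold.train + fold.val})
                covered.extend(fold.test)
            if mode in ("0D", "1DN", "1DA"):
                assert sorted(covered) == sorted(r.reaction_id for r in ds.records)

    def test_same_seed_identical_assignment(self):
        ds = grid_dataset()
        for mode in ("0D", "1DN", "1DA", "2D"):
            a = make_split(ds, mode, k=3, seed=11)
            b = make_split(ds, mode, k=3, seed=11)
            for fa, fb in zip(a.folds, b.folds):
                assert fa.train == fb.train and fa.val == fb.val and fa.test == fb.test
            c = make_split(ds, mode, k=3, seed=12)
            assert any(fa.test != fc.test for fa, fc in zip(a.folds, c.folds))


class TestErrorsAndSerialization:
    def test_too_few_entities(self):
        ds = grid_dataset(3, 6)
        with pytest.raises(SplitError):
            make_split(ds, "1DN", k=4, seed=0)

    def test_unknown_mode(self):
        with pytest.raises(SplitError):
            make_split(grid_dataset(), "3D", k=2, seed=0)

    def test_json_round_trip(self, tmp_path):
        split = make_split(grid_dataset(), "2D", k=2, seed=5)
        p = tmp_path / "s.json"
        split.to_json(p)
        loaded = SplitAssignment.from_json(p)
        assert loaded.mode == split.mode and loaded.seed == split.seed
        assert [f.test for f in loaded.folds] == [f.test for f in split.folds]

    def test_entity_identity_is_canonical_structure(self):
        # same pyridine written two ways must land on the same side
        records = [
            make_record(0, arene="c1ccncc1"),
            make_record(1, arene="C1=CC=NC=C1"),
            make_record(2, arene="c1cnc(C)nc1"),
            make_record(3, arene="c1ccc2ncccc2c1"),
            make_record(4, arene="c1cc(F)ncc1"),
        ]
        ds = ReactionDataset(records)
        split = make_split(ds, "1DN", k=2, seed=0)
        for fold in split.folds:
            both = {"R0000", "R0001"}
            assert both <= set(fold.test) or not (both & set(fold.test))
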