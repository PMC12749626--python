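"""SURF dialect I/O, yield arithmetic and dataset summaries."""

import numpy as np
import pandas as pd
import pytest

from reactionfunnel.errors import EmptyInputError, SchemaError, StructureError, ValidationError
from reactionfunnel.surf import (
    ReactionDataset,
    binary_outcome,
    dataset_summary,
    read_surf,
    total_yield,
    write_surf,
)

from conftest import make_record


def datasets_equal(a: ReactionDataset, b: ReactionDataset) -> bool:
    if len(a) != len(b):
        return False
    for ra, rb in zip(a.records, b.records):
        for field in ("reaction_id", "arene", "acid", "catalyst", "additive",
                      "reagent", "solvent", "atmosphere"):
            if getattr(ra, field) != getattr(rb, field):
                return False
        for field in ("temperature", "time", "concentration", "scale",
                      "yield_mono", "yield_di"):
            if abs(getattr(ra, field) - getattr(rb, field)) > 1e-9:
                return False
    return True


class TestRoundTrip:
    def test_six_record_round_trip(self, six_record_dataset, tmp_path):
        path = tmp_path / "x.surf"
        write_surf(six_record_dataset, path)
        assert datasets_equal(read_surf(path), six_record_dataset)

    def test_empty_dataset_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.surf"
        write_surf(ReactionDataset([]), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("rxn_id\t")
        assert len(read_surf(path)) == 0

    def test_yields_serialized_as_percent(self, tmp_path):
        ds = ReactionDataset([make_record(0, yield_mono=0.305, yield_di=0.0)])
        path = tmp_path / "pct.surf"
        write_surf(ds, path)
        df = pd.read_csv(path, sep="\t")
        assert df.loc[0, "product_1_yield"] == pytest.approx(30.5)

    def test_random_datasets_round_trip(self, rng, tmp_path):
        for trial in range(5):
            n = int(rng.integers(1, 12))
            records = [
                make_record(
                    i,
                    yield_mono=float(np.round(rng.uniform(0, 0.7), 4)),
                    yield_di=float(np.round(rng.uniform(0, 0.2), 4)),
                    temperature=float(rng.choice([60, 80, 100])),
                )
                for i in range(n)
            ]
            ds = ReactionDataset(records)
            path = tmp_path / f"t{trial}.surf"
            write_surf(ds, path)
            assert datasets_equal(read_surf(path), ds)


class TestReadErrors:
    def test_missing_catalyst_column_is_schema_error(self, six_record_dataset, tmp_path):
        path = tmp_path / "x.surf"
        write_surf(six_record_dataset, path)
        df = pd.read_csv(path, sep="\t").drop(columns=["catalyst_1_smiles"])
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="catalyst_1_smiles"):
            read_surf(path)

    def test_negative_yield_rejected(self, six_record_dataset, tmp_path):
        path = tmp_path / "x.surf"
        write_surf(six_record_dataset, path)
        df = pd.read_csv(path, sep="\t")
        df.loc[0, "product_1_yield"] = -5.0
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError, match="negative yield"):
            read_surf(path)

    def test_bad_smiles_names_reaction(self, six_record_dataset, tmp_path):
        path = tmp_path / "x.surf"
        write_surf(six_record_dataset, path)
        df = pd.read_csv(path, sep="\t")
        df.loc[2, "startingmat_1_smiles"] = "not_a_structure(("
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(StructureError, match="R0002"):
            read_surf(path)

    def test_column_mapping_loads_foreign_headers(self, six_record_dataset, tmp_path):
        path = tmp_path / "x.surf"
        write_surf(six_record_dataset, path)
        df = pd.read_csv(path, sep="\t").rename(columns={"rxn_id": "reaction_identifier"})
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError):
            read_surf(path)
        ds = read_surf(path, column_map={"rxn_id": "reaction_identifier"})
        assert datasets_equal(ds, six_record_dataset)

    def test_missing_di_column_defaults_to_zero(self, six_record_dataset, tmp_path):
        path = tmp_path / "x.surf"
        write_surf(six_record_dataset, path)
        df = pd.read_csv(path, sep="\t").drop(columns=["product_2_yield"])
        df.to_csv(path, sep="\t", index=False)
        assert all(r.yield_di == 0.0 for r in read_surf(path).records)


class TestYieldArithmetic:
    @pytest.mark.parametrize(
        "mono,di,expected",
        [(0.25, 0.05, 0.30), (0.0, 0.0, 0.0), (0.9, 0.2, 1.0), (0.5, 0.5, 1.0)],
    )
    def test_total_yield_sums_and_clips(self, mono, di, expected):
        assert total_yield(make_record(yield_mono=mono, yield_di=di)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "total,expected",
        [(0.05, 1), (0.049, 0), (0.051, 1), (0.0, 0), (1.0, 1)],
    )
    def test_binary_outcome_threshold_inclusive(self, total, expected):
        rec = make_record(yield_mono=total, yield_di=0.0)
        assert binary_outcome(rec) == expected

    def test_binary_outcome_rejects_bad_threshold(self):
        with pytest.raises(ValueError):
            binary_outcome(make_record(), threshold=1.5)

    def test_total_yield_monotone_in_components(self, rng):
        for _ in range(50):
            m, d = rng.uniform(0, 0.8, size=2)
            eps = rng.uniform(0, 0.2)
            base = total_yield(make_record(yield_mono=m, yield_di=d))
            assert total_yield(make_record(yield_mono=m + eps, yield_di=d)) >= base
            assert 0.0 <= base <= 1.0


class TestSummary:
    def test_counts_positives(self):
        records = [
            make_record(i, yield_mono=0.2 if i < 3 else 0.0, yield_di=0.0)
            for i in range(10)
        ]
        s = dataset_summary(ReactionDataset(records))
        assert s.n == 10
        assert s.positive_rate == pytest.approx(0.3)

    def test_all_negative_dataset(self):
        records = [make_record(i, yield_mono=0.01, yield_di=0.0) for i in range(4)]
        s = dataset_summary(ReactionDataset(records))
        assert s.positive_rate == 0.0
        assert s.yield_histogram[0].sum() == 0

    def test_empty_dataset_raises(self):
        with pytest.raises(EmptyInputError):
            dataset_summary(ReactionDataset([]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            ReactionDataset([make_record(1), make_record(1)])
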