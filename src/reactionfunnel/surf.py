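"""Reading, writing and summarizing reaction tables in a SURF dialect.

SURF (Simple User-Friendly Reaction Format) is a tab-separated, human- and
machine-readable reaction record layout: one row per reaction carrying the
structures of both coupling partners as SMILES, the categorical reaction
conditions (catalyst, additive, oxidant/reagent, solvent, atmosphere), the
numeric process variables (temperature, time, concentration, scale) and the
observed mono-/di-alkylation yields.

Yields are stored internally as fractions in [0, 1] and serialized as
percent, the convention of the tabular dialect. A column-mapping dictionary
lets externally produced files with different header spellings be loaded
without editing the file.
"""

from __future__ import annotations

import dataclasses
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import EmptyInputError, SchemaError, StructureError, ValidationError

RDLogger.DisableLog("rdApp.*")

#: Condition categories that form the one-hot vocabulary, in serialization order.
CONDITION_CATEGORIES = ("reagent", "solvent", "catalyst", "additive", "atmosphere")

#: Canonical column layout of the dialect. Values are (column name, required).
SURF_COLUMNS: tuple[tuple[str, bool], ...] = (
    ("rxn_id", True),
    ("startingmat_1_smiles", True),
    ("startingmat_2_smiles", True),
    ("product_1_smiles", False),
    ("catalyst_1_smiles", True),
    ("additive_1_smiles", True),
    ("reagent_1_smiles", True),
    ("solvent_1_smiles", True),
    ("atmosphere", True),
    ("temperature_deg_c", True),
    ("time_h", True),
    ("concentration_moll", True),
    ("scale_mol", True),
    ("product_1_yield", True),
    ("product_2_yield", False),
)


@dataclasses.dataclass
class ReactionRecord:
    """One SURF row: a single Minisci-type alkylation experiment."""

    reaction_id: str
    arene: str
    acid: str
    catalyst: str
    additive: str
    reagent: str
    solvent: str
    atmosphere: str
    temperature: float = 80.0
    time: float = 18.0
    concentration: float = 0.016
    scale: float = 8e-7
    yield_mono: float = 0.0
    yield_di: float = 0.0
    product: str | None = None

    def validate(self, parse_structures: bool = True) -> None:
        if self.yield_mono < 0 or self.yield_di < 0:
            raise ValidationError(
                f"negative yield in reaction {self.reaction_id!r}: "
                f"mono={self.yield_mono}, di={self.yield_di}"
            )
        for cat in CONDITION_CATEGORIES:
            if not str(getattr(self, cat)).strip():
                raise ValidationError(
                    f"empty {cat} label in reaction {self.reaction_id!r}"
                )
        if parse_structures:
            for role in ("arene", "acid"):
                smi = getattr(self, role)
                if Chem.MolFromSmiles(smi) is None:
                    raise StructureError(
                        f"unparsable {role} SMILES {smi!r} in reaction "
                        f"{self.reaction_id!r}"
                    )


@dataclasses.dataclass
class ReactionDataset:
    """Ordered reaction records plus the per-category condition vocabulary."""

    records: list[ReactionRecord]
    condition_vocabulary: "OrderedDict[str, list[str]]" = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.condition_vocabulary is None:
            self.condition_vocabulary = build_vocabulary(self.records)
        ids = [r.reaction_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValidationError(
                f"duplicate reaction_ids: {list(dup[dup > 1].index[:5])}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, reaction_ids: Iterable[str]) -> "ReactionDataset":
        wanted = set(reaction_ids)
        return ReactionDataset(
            [r for r in self.records if r.reaction_id in wanted],
            condition_vocabulary=self.condition_vocabulary,
        )


def build_vocabulary(records: Iterable[ReactionRecord]) -> "OrderedDict[str, list[str]]":
    """Per-category label lists in first-appearance order."""
    vocab: OrderedDict[str, list[str]] = OrderedDict(
        (cat, []) for cat in CONDITION_CATEGORIES
    )
    for rec in records:
        for cat in CONDITION_CATEGORIES:
            label = str(getattr(rec, cat))
            if label not in vocab[cat]:
                vocab[cat].append(label)
    return vocab


_FIELD_BY_COLUMN = {
    "rxn_id": "reaction_id",
    "startingmat_1_smiles": "arene",
    "startingmat_2_smiles": "acid",
    "product_1_smiles": "product",
    "catalyst_1_smiles": "catalyst",
    "additive_1_smiles": "additive",
    "reagent_1_smiles": "reagent",
    "solvent_1_smiles": "solvent",
    "atmosphere": "atmosphere",
    "temperature_deg_c": "temperature",
    "time_h": "time",
    "concentration_moll": "concentration",
    "scale_mol": "scale",
}


def read_surf(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    yield_unit: str = "percent",
    parse_structures: bool = True,
) -> ReactionDataset:
    """Load a SURF tab-separated file into a :class:`ReactionDataset`.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Optional mapping ``{canonical column -> header used in the file}``
        for loading externally produced SURF exports whose headers differ
        from the dialect here.
    yield_unit
        ``"percent"`` (dialect default), ``"fraction"``, or ``"auto"``
        (percent if any yield value exceeds 1.5, else fraction).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if column_map:
        inverse = {v: k for k, v in column_map.items()}
        df = df.rename(columns=inverse)
    for col, required in SURF_COLUMNS:
        if required and col not in df.columns:
            raise SchemaError(f"missing required SURF column {col!r} in {path}")
    if "product_2_yield" not in df.columns:
        df["product_2_yield"] = "0"
    if "product_1_smiles" not in df.columns:
        df["product_1_smiles"] = ""

    def _yields(raw: pd.Series) -> np.ndarray:
        vals = pd.to_numeric(raw.replace("", "0"), errors="raise").to_numpy(float)
        return vals

    y1 = _yields(df["product_1_yield"])
    y2 = _yields(df["product_2_yield"])
    unit = yield_unit
    if unit == "auto":
        unit = "percent" if max(y1.max(initial=0), y2.max(initial=0)) > 1.5 else "fraction"
    if unit == "percent":
        y1, y2 = y1 / 100.0, y2 / 100.0
    elif unit != "fraction":
        raise ValueError(f"unknown yield_unit {yield_unit!r}")

    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        rec = ReactionRecord(
            reaction_id=str(row["rxn_id"]),
            arene=str(row["startingmat_1_smiles"]),
            acid=str(row["startingmat_2_smiles"]),
            product=str(row["product_1_smiles"]) or None,
            catalyst=str(row["catalyst_1_smiles"]),
            additive=str(row["additive_1_smiles"]),
            reagent=str(row["reagent_1_smiles"]),
            solvent=str(row["solvent_1_smiles"]),
            atmosphere=str(row["atmosphere"]),
            temperature=float(row["temperature_deg_c"]),
            time=float(row["time_h"]),
            concentration=float(row["concentration_moll"]),
            scale=float(row["scale_mol"]),
            yield_mono=float(y1[i]),
            yield_di=float(y2[i]),
        )
        rec.validate(parse_structures=parse_structures)
        records.append(rec)
    return ReactionDataset(records)


def write_surf(dataset: ReactionDataset, path: str | Path) -> None:
    """Serialize a dataset in the tab-separated dialect (yields as percent)."""
    rows = []
    for r in dataset.records:
        rows.append(
            {
                "rxn_id": r.reaction_id,
                "startingmat_1_smiles": r.arene,
                "startingmat_2_smiles": r.acid,
                "product_1_smiles": r.product or "",
                "catalyst_1_smiles": r.catalyst,
                "additive_1_smiles": r.additive,
                "reagent_1_smiles": r.reagent,
                "solvent_1_smiles": r.solvent,
                "atmosphere": r.atmosphere,
                "temperature_deg_c": r.temperature,
                "time_h": r.time,
                "concentration_moll": r.concentration,
                "scale_mol": r.scale,
                "product_1_yield": r.yield_mono * 100.0,
                "product_2_yield": r.yield_di * 100.0,
            }
        )
    columns = [c for c, _ in SURF_COLUMNS]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def total_yield(record: ReactionRecord) -> float:
    """Total alkylation yield: mono + di, clipped at 1.

    LC-MS area percentages can slightly oversum, hence the clip rather than
    an error.
    """
    return min(1.0, record.yield_mono + record.yield_di)


def binary_outcome(record: ReactionRecord, threshold: float = 0.05) -> int:
    """1 if the reaction is 'positive' (total yield >= threshold), else 0.

    The detection threshold defaults to 5% LC-MS yield; the boundary is
    inclusive.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return int(total_yield(record) >= threshold)


@dataclasses.dataclass
class DatasetSummary:
    n: int
    positive_rate: float
    yield_histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin edges), positives only
    coverage: pd.DataFrame  # arene x acid screened-combination counts

    def as_dict(self) -> dict:
        counts, edges = self.yield_histogram
        return {
            "n": self.n,
            "positive_rate": self.positive_rate,
            "yield_histogram": {
                "counts": counts.tolist(),
                "bin_edges": edges.tolist(),
            },
            "n_arenes": int(self.coverage.shape[0]),
            "n_acids": int(self.coverage.shape[1]),
            "screened_combinations": int((self.coverage.to_numpy() > 0).sum()),
        }


def dataset_summary(
    dataset: ReactionDataset,
    threshold: float = 0.05,
    bins: int = 10,
) -> DatasetSummary:
    """Binary-outcome and coverage statistics of a reaction dataset."""
    if len(dataset) == 0:
        raise EmptyInputError("cannot summarize an empty dataset")
    totals = np.array([total_yield(r) for r in dataset])
    labels = totals >= threshold
    positives = totals[labels]
    hist = np.histogram(positives, bins=bins, range=(0.0, 1.0))
    coverage = (
        pd.DataFrame(
            {"arene": [r.arene for r in dataset], "acid": [r.acid for r in dataset]}
        )
        .groupby(["arene", "acid"])
        .size()
        .unstack(fill_value=0)
    )
    return DatasetSummary(
        n=len(dataset),
        positive_rate=float(labels.mean()),
        yield_histogram=hist,
        coverage=coverage,
    )
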