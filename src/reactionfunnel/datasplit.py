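"""Cross-validation splits probing four extrapolation regimes.

The splits control which reaction components may be shared between train
and test partitions:

- ``0D``  random split over reactions (interpolation: both coupling
  partners seen during training, only the combination may be new);
- ``1DN`` entity split over N-arenes (every test arene unseen in training);
- ``1DA`` entity split over carboxylic acids;
- ``2D``  simultaneous entity split over both components; reactions with
  exactly one held-out component belong to neither side of that fold.

Entity identity is the canonicalized structure, not any external ID, so the
same compound under two labels cannot leak across the partition.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from rdkit import Chem

from .errors import SplitError
from .surf import ReactionDataset

MODES = ("0D", "1DN", "1DA", "2D")


@dataclasses.dataclass
class Fold:
    train: list[str]
    val: list[str]
    test: list[str]


@dataclasses.dataclass
class SplitAssignment:
    mode: str
    seed: int
    folds: list[Fold]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mode": self.mode,
            "seed": self.seed,
            "folds": [dataclasses.asdict(f) for f in self.folds],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitAssignment":
        payload = json.loads(Path(path).read_text())
        return cls(
            mode=payload["mode"],
            seed=payload["seed"],
            folds=[Fold(**f) for f in payload["folds"]],
        )


def _canonical(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else smiles


def _partition(items: list, k: int, rng: np.random.Generator) -> list[list]:
    """Seeded shuffle, then round-robin distribution of the remainder."""
    order = [items[i] for i in rng.permutation(len(items))]
    return [order[i::k] for i in range(k)]


def _carve_validation(
    train_ids: list[str], rng: np.random.Generator, val_fraction: float
) -> tuple[list[str], list[str]]:
    n_val = max(1, int(round(val_fraction * len(train_ids))))
    if n_val >= len(train_ids):
        raise SplitError("training partition too small to carve a validation set")
    perm = rng.permutation(len(train_ids))
    val = sorted(train_ids[i] for i in perm[:n_val])
    train = sorted(train_ids[i] for i in perm[n_val:])
    return train, val


def make_split(
    dataset: ReactionDataset,
    mode: str,
    k: int = 4,
    seed: int = 0,
    val_fraction: float = 0.1,
) -> SplitAssignment:
    """Build a k-fold assignment under one of the four extrapolation modes.

    Within each fold the validation set (for early stopping) is carved at
    random from the training partition.
    """
    mode = mode.upper()
    if mode not in MODES:
        raise SplitError(f"unknown split mode {mode!r}; expected one of {MODES}")
    if len(dataset) == 0:
        raise SplitError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    ids = [r.reaction_id for r in dataset.records]
    arene_of = {r.reaction_id: _canonical(r.arene) for r in dataset.records}
    acid_of = {r.reaction_id: _canonical(r.acid) for r in dataset.records}

    folds: list[Fold] = []
    if mode == "0D":
        test_sets = _partition(ids, k, rng)
        for test in test_sets:
            rest = [i for i in ids if i not in set(test)]
            train, val = _carve_validation(rest, rng, val_fraction)
            folds.append(Fold(train=train, val=val, test=sorted(test)))
    elif mode in ("1DN", "1DA"):
        entity_of = arene_of if mode == "1DN" else acid_of
        entities = sorted(set(entity_of.values()))
        if len(entities) < k:
            raise SplitError(
                f"{mode} split needs >= {k} distinct entities, found {len(entities)}"
            )
        held_sets = _partition(entities, k, rng)
        for held in held_sets:
            held = set(held)
            test = [i for i in ids if entity_of[i] in held]
            rest = [i for i in ids if entity_of[i] not in held]
            train, val = _carve_validation(rest, rng, val_fraction)
            folds.append(Fold(train=train, val=val, test=sorted(test)))
    else:  # 2D
        arenes = sorted(set(arene_of.values()))
        acids = sorted(set(acid_of.values()))
        if len(arenes) < k or len(acids) < k:
            raise SplitError(
                f"2D split needs >= {k} distinct arenes and acids "
                f"(found {len(arenes)} arenes, {len(acids)} acids)"
            )
        arene_sets = _partition(arenes, k, rng)
        acid_sets = _partition(acids, k, rng)
        for held_a, held_b in zip(arene_sets, acid_sets):
            held_a, held_b = set(held_a), set(held_b)
            test = [i for i in ids if arene_of[i] in held_a and acid_of[i] in held_b]
            rest = [
                i
                for i in ids
                if arene_of[i] not in held_a and acid_of[i] not in held_b
            ]
            if not test:
                raise SplitError(
                    "2D fold has an empty test set; reduce k or increase coverage"
                )
            train, val = _carve_validation(rest, rng, val_fraction)
            folds.append(Fold(train=train, val=val, test=sorted(test)))
    return SplitAssignment(mode=mode, seed=seed, folds=folds)
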