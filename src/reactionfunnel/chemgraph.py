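"""Featurized molecular graphs and reaction-condition encodings.

Molecules enter the reaction model as graphs over *explicit-hydrogen* atom
sets: each atom carries a 20-bit one-hot feature vector (12 element types,
ring membership, aromaticity, 4 hybridization states), edges are covalent
bonds, and — in 3D mode — each molecule additionally carries an ensemble of
ETKDG-embedded, UFF-minimized conformers whose inter-atomic distances are
encoded with a sine/cosine Fourier basis.

Categorical reaction conditions (reagent, solvent, catalyst, additive,
atmosphere) are concatenated per-category one-hots over a
:class:`ConditionVocabulary` built from the training data.
"""

from __future__ import annotations

import dataclasses
from collections import OrderedDict
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .errors import (
    ConformerError,
    EmptyInputError,
    StructureError,
    UnsupportedAtomError,
    VocabularyError,
)
from .surf import CONDITION_CATEGORIES, ReactionRecord

ELEMENTS = ("H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "Si", "Se")
HYBRIDIZATIONS = ("SP3", "SP2", "SP", "S")
ATOM_FEATURE_DIM = len(ELEMENTS) + 2 + 2 + len(HYBRIDIZATIONS)  # 20

_ELEMENT_INDEX = {e: i for i, e in enumerate(ELEMENTS)}
_HYB_INDEX = {h: i for i, h in enumerate(HYBRIDIZATIONS)}


def featurize_atom(
    element: str, in_ring: bool, aromatic: bool, hybridization: str
) -> np.ndarray:
    """One-hot atom feature vector of length 20 with exactly 4 bits set."""
    if element not in _ELEMENT_INDEX:
        raise UnsupportedAtomError(
            f"element {element!r} is outside the supported alphabet {ELEMENTS}"
        )
    if hybridization not in _HYB_INDEX:
        raise UnsupportedAtomError(
            f"hybridization {hybridization!r} not one of {HYBRIDIZATIONS}"
        )
    vec = np.zeros(ATOM_FEATURE_DIM)
    vec[_ELEMENT_INDEX[element]] = 1.0
    vec[12 + (1 if in_ring else 0)] = 1.0
    vec[14 + (1 if aromatic else 0)] = 1.0
    vec[16 + _HYB_INDEX[hybridization]] = 1.0
    return vec


def _hybridization_label(atom: Chem.Atom) -> str:
    name = str(atom.GetHybridization())
    if name in ("SP3", "SP2", "SP", "S"):
        return name
    # Unhybridized / degenerate centers (e.g. free H, UNSPECIFIED) -> S.
    if name in ("UNSPECIFIED", "OTHER"):
        return "S"
    raise UnsupportedAtomError(
        f"hybridization {name} of atom {atom.GetSymbol()} is unsupported"
    )


@dataclasses.dataclass
class MolecularGraph:
    """Explicit-H molecular graph with one-hot atom features.

    ``edges`` holds each covalent bond once as an (i, j) pair; message
    passing uses both directions. ``conformers`` is an optional
    (n_conformers, n_atoms, 3) coordinate array in Angstrom.
    """

    atom_features: np.ndarray  # (n_atoms, 20)
    edges: np.ndarray  # (n_bonds, 2) int
    conformers: np.ndarray | None = None  # (n_conf, n_atoms, 3)
    smiles: str | None = None

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def directed_edges(self) -> np.ndarray:
        """Both directions of every bond, shape (2*n_bonds, 2)."""
        if self.n_edges == 0:
            return np.zeros((0, 2), dtype=int)
        return np.concatenate([self.edges, self.edges[:, ::-1]], axis=0)


def mol_to_graph(
    smiles: str,
    with_conformers: bool = False,
    n_conformers: int = 10,
    seed: int = 0,
    max_embed_retries: int = 5,
) -> MolecularGraph:
    """Parse a SMILES into a featurized graph, optionally with 3D conformers.

    Hydrogens are made explicit before featurization (H is a first-class
    atom type). Conformers are embedded with ETKDG at a fixed seed and
    UFF-minimized; embedding is retried with derived seeds up to
    ``max_embed_retries`` times before raising :class:`ConformerError`.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparsable SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    feats = np.stack(
        [
            featurize_atom(
                a.GetSymbol(), a.IsInRing(), a.GetIsAromatic(), _hybridization_label(a)
            )
            for a in mol.GetAtoms()
        ]
    )
    edges = np.array(
        [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()], dtype=int
    ).reshape(-1, 2)

    conformers = None
    if with_conformers:
        conformers = _embed_conformers(mol, n_conformers, seed, max_embed_retries)
    return MolecularGraph(feats, edges, conformers, smiles=smiles)


def _embed_conformers(
    mol: Chem.Mol, n_conformers: int, seed: int, max_retries: int
) -> np.ndarray:
    params = AllChem.ETKDGv3()
    for attempt in range(max_retries):
        params.randomSeed = int(seed + 1 + attempt * 7919) % (2**31 - 1)
        mol.RemoveAllConformers()
        ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_conformers, params=params)
        if len(ids) == n_conformers:
            AllChem.UFFOptimizeMoleculeConfs(mol)
            return np.stack(
                [mol.GetConformer(i).GetPositions() for i in ids]
            )
    raise ConformerError(
        f"could not embed {n_conformers} conformers for "
        f"{Chem.MolToSmiles(Chem.RemoveHs(mol))!r} after {max_retries} attempts"
    )


class ConditionVocabulary:
    """Ordered label lists per condition category, with optional UNK levels.

    ``unk_categories`` lists categories for which an unknown label maps to a
    dedicated trailing UNK slot instead of raising; disabled by default so
    that a typo cannot silently collapse an extrapolation experiment.
    """

    def __init__(
        self,
        labels: Mapping[str, Sequence[str]],
        unk_categories: Sequence[str] = (),
    ):
        self.labels: "OrderedDict[str, list[str]]" = OrderedDict()
        for cat in CONDITION_CATEGORIES:
            if cat not in labels:
                raise VocabularyError(f"missing condition category {cat!r}")
            self.labels[cat] = list(labels[cat])
        self.unk_categories = frozenset(unk_categories)
        unknown = self.unk_categories - set(CONDITION_CATEGORIES)
        if unknown:
            raise VocabularyError(f"unknown UNK categories {sorted(unknown)}")

    def block_size(self, category: str) -> int:
        return len(self.labels[category]) + (1 if category in self.unk_categories else 0)

    @property
    def dim(self) -> int:
        return sum(self.block_size(cat) for cat in self.labels)

    def index(self, category: str, label: str) -> int:
        try:
            return self.labels[category].index(label)
        except ValueError:
            if category in self.unk_categories:
                return len(self.labels[category])
            raise VocabularyError(
                f"label {label!r} not in vocabulary for category {category!r}"
            ) from None


def encode_conditions(record: ReactionRecord, vocab: ConditionVocabulary) -> np.ndarray:
    """Concatenated per-category one-hot; exactly one bit set per block."""
    blocks = []
    for cat in CONDITION_CATEGORIES:
        block = np.zeros(vocab.block_size(cat))
        block[vocab.index(cat, str(getattr(record, cat)))] = 1.0
        blocks.append(block)
    return np.concatenate(blocks)


def default_fourier_frequencies(k: int = 16) -> np.ndarray:
    """Geometrically spaced angular frequencies (1/Angstrom).

    Chosen so the half-periods pi/f span roughly 0.5-12 A, covering covalent
    bond lengths up to through-space contact distances.
    """
    half_period = np.geomspace(0.5, 12.0, k)
    return np.pi / half_period


def fourier_distance(r, frequencies: np.ndarray) -> np.ndarray:
    """Sine/cosine positional encoding of non-negative scalar distance(s).

    For scalar ``r`` returns ``[sin(f_1 r) ... sin(f_K r),
    cos(f_1 r) ... cos(f_K r)]`` (length 2K); an array of distances gains a
    trailing feature axis.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    arg = r[..., None] * np.asarray(frequencies)
    return np.concatenate([np.sin(arg), np.cos(arg)], axis=-1)


def export_conformers_sdf(
    smiles: str, path, n_conformers: int = 10, seed: int = 0
) -> int:
    """Embed a conformer ensemble and write it as a multi-record SDF.

    Returns the number of conformers written; intended for visual
    inspection of what the 3D mode actually sees.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparsable SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    _embed_conformers(mol, n_conformers, seed, max_retries=5)
    writer = Chem.SDWriter(str(path))
    try:
        for conf in mol.GetConformers():
            writer.write(mol, confId=conf.GetId())
    finally:
        writer.close()
    return n_conformers


def graph_distances(graph: MolecularGraph, conformer: int) -> np.ndarray:
    """Per-directed-edge Euclidean distances for one conformer."""
    if graph.conformers is None:
        raise EmptyInputError("graph has no conformers")
    coords = graph.conformers[conformer]
    de = graph.directed_edges()
    diff = coords[de[:, 0]] - coords[de[:, 1]]
    return np.sqrt((diff**2).sum(axis=1))
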