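"""Deterministic toy scorers for pipeline testing.

These stand-ins let the funnel run end-to-end without the external
structure-based potency model or proprietary ADME models, which are
consumed only through the scorer plug-in contract. They are *synthetic*:
cheap descriptor-driven heuristics plus a stable structure hash for spread.
They make no claim to reproduce any published score distribution.
"""

from __future__ import annotations

import hashlib

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors


def _canonical(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    return mol


def _stable_unit(smiles: str, salt: str) -> float:
    """Deterministic pseudo-uniform in [0, 1) from the canonical structure."""
    key = Chem.MolToSmiles(_canonical(smiles)) + "|" + salt
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


def synthetic_potency(smiles: str) -> float:
    """Pseudo-pIC50 in roughly [4, 10.5]: size/lipophilicity plus hash spread."""
    mol = _canonical(smiles)
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    base = 4.0 + 3.0 * min(mw, 500.0) / 500.0 + 0.3 * max(min(logp, 5.0), -1.0)
    return base + 2.0 * _stable_unit(smiles, "potency") - 1.0


def synthetic_yield(smiles: str) -> float:
    """Pseudo reaction yield in [0, 1): structure-hashed, heavier products
    slightly disfavored. For exercising the funnel without a trained model."""
    mol = _canonical(smiles)
    mw = Descriptors.MolWt(mol)
    size_penalty = min(mw, 600.0) / 600.0 * 0.3
    return max(0.0, _stable_unit(smiles, "yield") * 0.8 - size_penalty + 0.1)


def toy_logd(smiles: str) -> float:
    """Crippen LogP as a LogD surrogate (ignores ionization)."""
    return float(Crippen.MolLogP(_canonical(smiles)))


def toy_lysa(smiles: str) -> float:
    """Pseudo kinetic solubility in ug/mL, decreasing with lipophilicity."""
    logd = toy_logd(smiles)
    return max(0.1, 500.0 * 10 ** (-0.4 * logd) * (0.5 + _stable_unit(smiles, "lysa")))


def toy_pgp(smiles: str) -> float:
    """Pseudo P-gp efflux ratio, increasing with polar surface area."""
    tpsa = Descriptors.TPSA(_canonical(smiles))
    return 0.5 + tpsa / 60.0 + 1.5 * _stable_unit(smiles, "pgp")


def toy_pampa(smiles: str) -> float:
    """Pseudo passive permeability in 1e-6 cm/s, decreasing with TPSA."""
    tpsa = Descriptors.TPSA(_canonical(smiles))
    return max(0.05, 30.0 * 10 ** (-tpsa / 120.0) * (0.5 + _stable_unit(smiles, "pampa")))
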