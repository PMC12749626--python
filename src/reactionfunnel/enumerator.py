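"""Virtual enumeration of Minisci C-H alkylation products.

A Minisci-type reaction couples an electron-poor N-heteroarene with an
alkyl radical generated by oxidative decarboxylation of a carboxylic acid.
In silico, the product is the scaffold with one aromatic C-H replaced by
the acid's decarboxylated alkyl fragment: the carboxyl carbon and both
oxygens are deleted and the alpha carbon is bonded to the chosen ring
position.

Radical addition favors positions ortho/para to the ring nitrogen; the
default site policy encodes exactly that preference and breaks ties by
canonical atom rank, so enumeration is deterministic.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .errors import EnumerationError, SiteError, StructureError

CARBOXYLIC_ACID = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")


@dataclasses.dataclass
class ScaffoldEntry:
    """An N-heteroaromatic hit molecule eligible for Minisci alkylation."""

    scaffold_id: str
    structure: str
    site: int | None = None  # atom index in the given SMILES ordering

    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.structure)
        if m is None:
            raise StructureError(
                f"unparsable scaffold {self.scaffold_id!r}: {self.structure!r}"
            )
        if not any(a.GetIsAromatic() and a.GetSymbol() == "N" for a in m.GetAtoms()):
            raise StructureError(
                f"scaffold {self.scaffold_id!r} has no aromatic nitrogen heterocycle"
            )
        return m


@dataclasses.dataclass
class AcidEntry:
    """A carboxylic acid radical precursor with its filter descriptors."""

    acid_id: str
    structure: str
    fsp3: float = 0.0
    mw: float = 0.0

    @classmethod
    def from_smiles(cls, acid_id: str, smiles: str) -> "AcidEntry":
        m = Chem.MolFromSmiles(smiles)
        if m is None:
            raise StructureError(f"unparsable acid {acid_id!r}: {smiles!r}")
        if len(m.GetSubstructMatches(CARBOXYLIC_ACID)) != 1:
            raise StructureError(
                f"acid {acid_id!r} must contain exactly one carboxylic-acid group"
            )
        return cls(
            acid_id=acid_id,
            structure=smiles,
            fsp3=float(Descriptors.FractionCSP3(m)),
            mw=float(Descriptors.MolWt(m)),
        )


@dataclasses.dataclass
class VirtualProduct:
    scaffold_id: str
    acid_id: str
    product: str
    site: int


def filter_acids(
    acids: Iterable[AcidEntry], mw_max: float = 230.0, fsp3_min: float = 0.5
) -> list[AcidEntry]:
    """Keep sp3-rich acids below the molecular-weight cap.

    The weight bound is strict (``mw < mw_max``); the sp3-fraction bound is
    inclusive.
    """
    return [a for a in acids if a.mw < mw_max and a.fsp3 >= fsp3_min]


def _ring_distance(mol: Chem.Mol, ring: tuple[int, ...], a: int, b: int) -> int:
    """Steps between two atoms along a ring (shorter arc)."""
    ia, ib = ring.index(a), ring.index(b)
    d = abs(ia - ib)
    return min(d, len(ring) - d)


def candidate_sites(mol: Chem.Mol) -> list[tuple[int, int]]:
    """Aromatic C-H positions ortho or para to a ring nitrogen.

    Returns ``(atom index, ring distance to the nearest ring N)`` pairs,
    where the distance is 1 (ortho) or 3 (para).
    """
    sites: dict[int, int] = {}
    for ring in mol.GetRingInfo().AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if not all(a.GetIsAromatic() for a in atoms):
            continue
        n_positions = [i for i, a in zip(ring, atoms) if a.GetSymbol() == "N"]
        if not n_positions:
            continue
        for i, a in zip(ring, atoms):
            if a.GetSymbol() != "C" or a.GetTotalNumHs() < 1:
                continue
            dists = [_ring_distance(mol, ring, i, n) for n in n_positions]
            near = min((d for d in dists if d in (1, 3)), default=None)
            if near is not None:
                sites[i] = min(sites.get(i, 99), near)
    return sorted(sites.items())


def suggest_site(structure: str) -> int:
    """Pick the alkylation site on an azine scaffold.

    Radical addition is most favorable ortho to the ring nitrogen, then
    para; remaining ties are broken by lowest canonical atom rank, then by
    atom index, so the choice is deterministic.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureError(f"unparsable structure {structure!r}")
    sites = candidate_sites(mol)
    if not sites:
        raise SiteError(
            f"no aromatic C-H ortho/para to a ring nitrogen in {structure!r}"
        )
    ranks = list(Chem.CanonicalRankAtoms(mol))
    return min(sites, key=lambda s: (s[1], ranks[s[0]], s[0]))[0]


def alkylate(scaffold: Chem.Mol, site: int, acid: Chem.Mol) -> str:
    """Replace the H at `site` with the acid's decarboxylated alkyl fragment."""
    matches = acid.GetSubstructMatches(CARBOXYLIC_ACID)
    if len(matches) != 1:
        raise EnumerationError("acid must contain exactly one carboxylic-acid group")
    c_cooh, o_double, o_hydroxyl = matches[0]
    acid_c = acid.GetAtomWithIdx(c_cooh)
    alpha = [n.GetIdx() for n in acid_c.GetNeighbors() if n.GetIdx() not in (o_double, o_hydroxyl)]
    if not alpha:
        raise EnumerationError("formic acid has no alkyl fragment to transfer")
    site_atom = scaffold.GetAtomWithIdx(site)
    if not (site_atom.GetIsAromatic() and site_atom.GetSymbol() == "C"
            and site_atom.GetTotalNumHs() >= 1):
        raise EnumerationError(
            f"site {site} is not an aromatic carbon bearing a hydrogen"
        )
    offset = scaffold.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(scaffold, acid))
    combined.AddBond(site, offset + alpha[0], Chem.BondType.SINGLE)
    for idx in sorted((c_cooh, o_double, o_hydroxyl), reverse=True):
        combined.RemoveAtom(offset + idx)
    product = combined.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:  # pragma: no cover - depends on inputs
        raise EnumerationError(f"product failed to sanitize: {exc}") from exc
    expected_heavy = scaffold.GetNumHeavyAtoms() + acid.GetNumHeavyAtoms() - 3
    if product.GetNumHeavyAtoms() != expected_heavy:
        raise EnumerationError(
            "heavy-atom bookkeeping violated: product should equal "
            "scaffold + acid - CO2"
        )
    return Chem.MolToSmiles(product)


def enumerate_products(
    scaffolds: Sequence[ScaffoldEntry],
    acids: Sequence[AcidEntry],
    site_policy: str = "designated-or-suggest",
    multi_site: bool = False,
    deduplicate: bool = False,
) -> list[VirtualProduct]:
    """One product per (scaffold, acid) pair, scaffold-major ordering.

    ``site_policy``: ``"designated-or-suggest"`` uses the entry's site when
    given and falls back to :func:`suggest_site`; ``"suggest"`` always
    re-derives the site; ``"designated"`` requires an explicit site.

    ``multi_site=True`` expands every candidate ortho/para site instead of
    resolving one per scaffold (the headline |scaffolds| x |acids| count
    assumes single-site mode). ``deduplicate=True`` drops repeated
    canonical products, for library hygiene at the cost of the pair count.
    """
    products: list[VirtualProduct] = []
    acid_mols = []
    for a in acids:
        m = Chem.MolFromSmiles(a.structure)
        if m is None:
            raise StructureError(f"unparsable acid {a.acid_id!r}: {a.structure!r}")
        acid_mols.append(m)
    seen: set[str] = set()
    for s in scaffolds:
        mol = s.mol()
        if multi_site:
            sites = [i for i, _ in candidate_sites(mol)]
            if not sites:
                raise SiteError(f"no alkylation site on scaffold {s.scaffold_id!r}")
        elif site_policy == "suggest" or (
            site_policy == "designated-or-suggest" and s.site is None
        ):
            sites = [suggest_site(s.structure)]
        elif s.site is None:
            raise EnumerationError(
                f"scaffold {s.scaffold_id!r} has no designated site"
            )
        else:
            sites = [s.site]
        for a, am in zip(acids, acid_mols):
            for site in sites:
                try:
                    smi = alkylate(mol, site, am)
                except EnumerationError as exc:
                    raise EnumerationError(
                        f"enumeration failed for ({s.scaffold_id}, {a.acid_id}): {exc}"
                    ) from exc
                if deduplicate:
                    if smi in seen:
                        continue
                    seen.add(smi)
                products.append(
                    VirtualProduct(
                        scaffold_id=s.scaffold_id,
                        acid_id=a.acid_id,
                        product=smi,
                        site=site,
                    )
                )
    return products


# -- TSV plumbing ------------------------------------------------------------


def read_scaffolds(path: str | Path) -> list[ScaffoldEntry]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    entries = []
    for row in df.itertuples(index=False):
        site = getattr(row, "site", None)
        entries.append(
            ScaffoldEntry(
                scaffold_id=str(row.id),
                structure=str(row.smiles),
                site=None if site is None or pd.isna(site) else int(site),
            )
        )
    return entries


def read_acids(path: str | Path) -> list[AcidEntry]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    return [AcidEntry.from_smiles(str(r.id), str(r.smiles)) for r in df.itertuples(index=False)]


def write_products(products: Sequence[VirtualProduct], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "scaffold_id": p.scaffold_id,
                "acid_id": p.acid_id,
                "product_smiles": p.product,
                "site": p.site,
            }
            for p in products
        ]
    ).to_csv(path, sep="\t", index=False)
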