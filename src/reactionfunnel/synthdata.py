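"""Synthetic Minisci-style reaction datasets with a planted yield surface.

The generator emulates the structure of a plate-based alkylation screen:
a library of azine scaffolds crossed with sp3-rich carboxylic acids, each
screened combination occupying a full catalyst x additive condition plate
(six silver salts x four additive levels = 24 wells, with a single
persulfate oxidant, MeCN/H2O solvent and ambient atmosphere), and only a
fraction of the scaffold x acid grid actually screened.

The latent yield is additive in an arene effect, an acid effect, and a
catalyst x additive interaction, plus Gaussian noise, clipped to [0, 1]:

    y = clip01( base + a(arene) + b(acid) + c(catalyst, additive) + eps )

The base offset is calibrated on the sampled rows so that the fraction of
reactions with y >= 5% matches the target positive rate. Entity effects
are attached to molecular identity, which makes entity-held-out splits
genuinely harder than random splits: a model cannot know a(arene) for an
arene it never saw. Total yield is split into mono- and di-alkylation
components with di <= mono.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .enumerator import AcidEntry, ScaffoldEntry, suggest_site
from .errors import FunnelError, SiteError
from .funnel import CandidateScoreCard
from .surf import ReactionDataset, ReactionRecord

CATALYSTS = ("AgNO3", "AgBF4", "Ag-pTsOH", "AgCF3SO3", "AgCO2CH3", "AgSCF3")
ADDITIVES = ("TFA", "H2SO4", "HNO3", "none")
REAGENT = "(NH4)2S2O8"
SOLVENT = "MeCN/H2O 3:2"
ATMOSPHERE = "air"


@dataclasses.dataclass
class SyntheticSpec:
    n_arenes: int = 80
    n_acids: int = 59
    n_catalysts: int = 6
    n_additives: int = 4
    coverage_fraction: float = 0.12
    target_positive_rate: float = 0.30
    noise_sd: float = 0.05
    seed: int = 0
    n_reactions: int | None = None  # overrides coverage_fraction when set
    arene_effect_sd: float = 0.12
    acid_effect_sd: float = 0.10
    interaction_sd: float = 0.08
    base_yield: float | None = None  # overrides positive-rate calibration

    def __post_init__(self):
        for f in ("n_arenes", "n_acids", "n_catalysts", "n_additives"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if not 0.0 < self.coverage_fraction <= 1.0:
            raise ValueError("coverage_fraction must be in (0, 1]")
        if not 0.0 < self.target_positive_rate < 1.0:
            raise ValueError("target_positive_rate must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_catalysts > len(CATALYSTS) or self.n_additives > len(ADDITIVES):
            raise ValueError(
                f"at most {len(CATALYSTS)} catalysts and {len(ADDITIVES)} additives "
                "are available"
            )


# -- structure grammar -------------------------------------------------------

_CORES = (
    "c1cc{0}nc{1}c1{2}",        # pyridines
    "c1nc{0}nc{1}c1{2}",        # pyrimidines
    "c1cnc{0}c{1}n1",           # pyrazines
    "c1cc{0}c2nc{1}ccc2c1",     # quinolines
    "c1cc{0}c2c(c1)cc{1}nc2",   # isoquinolines
    "c1cc{0}c2ncc{1}n2c1",      # imidazopyridines
)

_SUBSTITUENTS = (
    "", "(C)", "(F)", "(Cl)", "(OC)", "(C(F)(F)F)", "(CC)", "(N)", "(C#N)",
    "(O)", "(C(C)C)",
)

_ACID_R_GROUPS = (
    "C", "CC", "CCC", "CC(C)C", "C(C)C", "C(C)(C)C", "CCCC", "C(C)CC",
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCOC1", "C1CCOCC1",
    "C1CCNCC1", "C1CCCNC1", "CC1CC1", "CC1CCC1", "C1CC1C", "C1CCC1C",
    "C(C)C1CC1", "CC(C)C1CC1", "C1(C)CCC1", "C1(C)CCCC1", "C1CC2(C1)CC2",
    "C1CC2(CC1)CC2", "CC1CCOC1", "CC1CCOCC1", "C1COC1", "CC1COC1",
)


def _valid_unique(smiles_iter, n: int, validator=None) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for smi in smiles_iter:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        if validator is not None and not validator(mol):
            continue
        seen.add(canon)
        out.append(smi)
        if len(out) == n:
            return out
    raise FunnelError(f"structure grammar exhausted after {len(out)}/{n} structures")


def generate_structures(
    spec: SyntheticSpec,
) -> tuple[list[ScaffoldEntry], list[AcidEntry]]:
    """Distinct azine scaffolds (with a designated site) and sp3-rich acids.

    Scaffolds are assembled from azine core templates with substituent
    draws; every scaffold resolves to a single alkylation site. Acids are
    alkyl/cycloalkyl carboxylic acids, all below 230 g/mol.
    """
    rng = np.random.default_rng(spec.seed)

    def scaffold_candidates():
        while True:
            core = _CORES[rng.integers(len(_CORES))]
            subs = [_SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))] for _ in range(3)]
            yield core.format(*subs)

    def has_site(mol) -> bool:
        try:
            suggest_site(Chem.MolToSmiles(mol))
            return True
        except SiteError:
            return False

    scaffold_smiles = _valid_unique(scaffold_candidates(), spec.n_arenes, has_site)
    scaffolds = [
        ScaffoldEntry(f"F{i + 1}", smi, site=suggest_site(smi))
        for i, smi in enumerate(scaffold_smiles)
    ]

    patterns = (
        "OC(=O){r}", "OC(=O)C(C){r}", "OC(=O)C(CC){r}", "OC(=O)C(O){r}",
        "OC(=O)CC{r}", "OC(=O)C(C)(C){r}", "OC(=O)CCC{r}", "OC(=O)C(C)C{r}",
    )

    def acid_candidates():
        # deterministic sweep over alkyl skeletons x alpha-decoration patterns
        for pat in patterns:
            for r in _ACID_R_GROUPS:
                yield pat.format(r=r)
        while True:
            pat = patterns[rng.integers(len(patterns))]
            r = _ACID_R_GROUPS[rng.integers(len(_ACID_R_GROUPS))]
            yield pat.format(r=r) + "C"  # homologated tail as a last resort

    def acid_ok(mol) -> bool:
        return Descriptors.MolWt(mol) < 230.0

    acid_smiles = _valid_unique(acid_candidates(), spec.n_acids, acid_ok)
    acids = [
        AcidEntry.from_smiles(f"A{i + 1}", smi) for i, smi in enumerate(acid_smiles)
    ]
    return scaffolds, acids


# -- dataset generation ------------------------------------------------------


@dataclasses.dataclass
class PlantedTruth:
    """The latent surface behind a generated dataset, for recovery tests."""

    base: float
    arene_effects: dict
    acid_effects: dict
    interaction: dict  # (catalyst, additive) -> effect
    latent: np.ndarray  # pre-clip latent yield per record


def generate_dataset(
    spec: SyntheticSpec, return_truth: bool = False
) -> ReactionDataset | tuple[ReactionDataset, PlantedTruth]:
    """Sample a screened subset of the arene x acid x condition grid."""
    rng = np.random.default_rng(spec.seed)
    scaffolds, acids = generate_structures(spec)
    catalysts = CATALYSTS[: spec.n_catalysts]
    additives = ADDITIVES[: spec.n_additives]
    n_cond = len(catalysts) * len(additives)

    pairs = list(itertools.product(range(len(scaffolds)), range(len(acids))))
    if spec.n_reactions is not None:
        n_rows = spec.n_reactions
        n_pairs = int(np.ceil(n_rows / n_cond))
    else:
        n_pairs = int(round(spec.coverage_fraction * len(pairs)))
        n_rows = n_pairs * n_cond
    if n_pairs == 0 or n_rows == 0:
        raise FunnelError("coverage too low: no reactions to generate")
    if n_pairs > len(pairs):
        raise FunnelError("requested more screened pairs than the grid holds")
    chosen = [pairs[i] for i in rng.choice(len(pairs), size=n_pairs, replace=False)]

    arene_fx = rng.normal(0.0, spec.arene_effect_sd, size=len(scaffolds))
    acid_fx = rng.normal(0.0, spec.acid_effect_sd, size=len(acids))
    inter_fx = rng.normal(0.0, spec.interaction_sd, size=(len(catalysts), len(additives)))

    rows = []
    for ai, bi in chosen:
        for ci, cat in enumerate(catalysts):
            for di, add in enumerate(additives):
                rows.append((ai, bi, ci, di))
    rows = rows[:n_rows]
    eps = rng.normal(0.0, spec.noise_sd, size=len(rows))
    latent_no_base = np.array(
        [arene_fx[a] + acid_fx[b] + inter_fx[c, d] for a, b, c, d in rows]
    ) + eps

    if spec.base_yield is not None:
        base = spec.base_yield
    else:
        # Place the 5% detection threshold at the (1 - target) quantile.
        base = 0.05 - float(
            np.quantile(latent_no_base, 1.0 - spec.target_positive_rate)
        )
    latent = base + latent_no_base
    totals = np.clip(latent, 0.0, 1.0)

    # Split into mono/di: occasional di-alkylation, never exceeding mono.
    has_di = rng.random(len(rows)) < 0.25
    di_frac = rng.uniform(0.0, 0.5, size=len(rows)) * has_di
    yield_di = totals * di_frac
    yield_mono = totals - yield_di

    records = []
    for i, (a, b, c, d) in enumerate(rows):
        records.append(
            ReactionRecord(
                reaction_id=f"R{i + 1:06d}",
                arene=scaffolds[a].structure,
                acid=acids[b].structure,
                catalyst=catalysts[c],
                additive=additives[d],
                reagent=REAGENT,
                solvent=SOLVENT,
                atmosphere=ATMOSPHERE,
                yield_mono=float(yield_mono[i]),
                yield_di=float(yield_di[i]),
            )
        )
    dataset = ReactionDataset(records)
    if not return_truth:
        return dataset
    truth = PlantedTruth(
        base=base,
        arene_effects={s.structure: float(v) for s, v in zip(scaffolds, arene_fx)},
        acid_effects={a.structure: float(v) for a, v in zip(acids, acid_fx)},
        interaction={
            (cat, add): float(inter_fx[c, d])
            for c, cat in enumerate(catalysts)
            for d, add in enumerate(additives)
        },
        latent=latent,
    )
    return dataset, truth


def generate_scorecards(n: int, seed: int = 0) -> list[CandidateScoreCard]:
    """Score cards with a known joint distribution for funnel tests.

    pIC50 ~ U(4, 10), predicted yield ~ U(0, 0.5), LogD ~ N(2, 1),
    LYSA ~ LogNormal(ln 50, 1), P-gp ratio ~ LogNormal(0, 0.5),
    PAMPA ~ LogNormal(ln 5, 0.8). Stage expectations follow in closed
    form, e.g. P(pIC50 >= 6) = 2/3.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    cards = []
    for i in range(n):
        cards.append(
            CandidateScoreCard(
                scaffold_id=f"S{i + 1}",
                acid_id=f"A{i + 1}",
                pic50_pred=float(rng.uniform(4.0, 10.0)),
                yield_pred=float(rng.uniform(0.0, 0.5)),
                logd=float(rng.normal(2.0, 1.0)),
                lysa=float(np.exp(rng.normal(np.log(50.0), 1.0))),
                pgp_ratio=float(np.exp(rng.normal(0.0, 0.5))),
                pampa=float(np.exp(rng.normal(np.log(5.0), 0.8))),
            )
        )
    return cards
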