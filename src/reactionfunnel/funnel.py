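"""Multi-dimensional optimization funnel for enumerated candidates.

Each virtual product carries a score card: predicted potency (pIC50),
predicted reaction yield (synthesizability proxy), and four ADME endpoints
(LogD, LYSA solubility in ug/mL, P-gp efflux ratio, PAMPA permeability in
1e-6 cm/s). The funnel applies staged inclusive thresholds:

  stage 1: pIC50 >= 6           (worth making at all)
  stage 2: ... and yield >= 5%  (synthetically accessible)
  stage 3: ... and pIC50 >= 8   (preferred candidates)

ADME windows, when configured, *annotate* the survivors rather than
eliminate them by default: hard sequential property cutoffs propagate model
error, so the final trade-off is left to ranking and human judgment. A
strict mode is available for users who do want a fourth elimination stage.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping, Sequence

from .errors import RegistrationError

ADME_ENDPOINTS = ("logd", "lysa", "pgp_ratio", "pampa")


@dataclasses.dataclass
class CandidateScoreCard:
    scaffold_id: str
    acid_id: str
    pic50_pred: float
    yield_pred: float
    logd: float | None = None
    lysa: float | None = None
    pgp_ratio: float | None = None
    pampa: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.scaffold_id, self.acid_id)

    def __post_init__(self):
        if not math.isfinite(self.pic50_pred):
            raise ValueError(f"non-finite pIC50 for {self.key}")
        if not 0.0 <= self.yield_pred <= 1.0:
            raise ValueError(
                f"yield_pred must be a fraction in [0, 1], got {self.yield_pred}"
            )


@dataclasses.dataclass
class FunnelConfig:
    potency_stage1_min: float = 6.0
    yield_min: float = 0.05
    potency_stage3_min: float = 8.0
    adme_windows: Mapping[str, tuple[float, float]] | None = None
    strict_adme: bool = False

    def __post_init__(self):
        if self.potency_stage3_min < self.potency_stage1_min:
            raise ValueError("stage-3 potency threshold must be >= stage-1 threshold")
        if not 0.0 <= self.yield_min <= 1.0:
            raise ValueError("yield_min must be a fraction in [0, 1]")
        if self.adme_windows:
            bad = set(self.adme_windows) - set(ADME_ENDPOINTS)
            if bad:
                raise ValueError(f"unknown ADME endpoints {sorted(bad)}")


@dataclasses.dataclass
class FunnelResult:
    stage1_ids: list[tuple[str, str]]
    stage2_ids: list[tuple[str, str]]
    stage3_ids: list[tuple[str, str]]
    stage4_ids: list[tuple[str, str]] | None  # strict-ADME survivors, if enabled
    ranked: list[CandidateScoreCard]
    adme_flags: dict  # key -> list of endpoints outside their window

    @property
    def counts(self) -> dict:
        out = {
            "input": len(self.ranked),
            "stage1_potency": len(self.stage1_ids),
            "stage2_synthesizable": len(self.stage2_ids),
            "stage3_potent": len(self.stage3_ids),
        }
        if self.stage4_ids is not None:
            out["stage4_adme"] = len(self.stage4_ids)
        return out


def _in_window(value: float | None, window: tuple[float, float]) -> bool:
    if value is None:
        return False
    lo, hi = window
    return lo <= value <= hi


def apply_funnel(
    cards: Sequence[CandidateScoreCard], config: FunnelConfig | None = None
) -> FunnelResult:
    """Run the staged filter cascade; all thresholds are inclusive (>=).

    The returned ranking covers *all* input cards, ordered by descending
    predicted potency, then descending predicted yield, then id.
    """
    config = config or FunnelConfig()
    stage1 = [c for c in cards if c.pic50_pred >= config.potency_stage1_min]
    stage2 = [c for c in stage1 if c.yield_pred >= config.yield_min]
    stage3 = [c for c in stage2 if c.pic50_pred >= config.potency_stage3_min]

    adme_flags: dict = {}
    stage4 = None
    if config.adme_windows:
        for c in stage3:
            out_of_window = [
                ep
                for ep, window in config.adme_windows.items()
                if not _in_window(getattr(c, ep), window)
            ]
            adme_flags[c.key] = out_of_window
        if config.strict_adme:
            stage4 = [c for c in stage3 if not adme_flags[c.key]]

    ranked = sorted(
        cards, key=lambda c: (-c.pic50_pred, -c.yield_pred, c.scaffold_id, c.acid_id)
    )
    return FunnelResult(
        stage1_ids=[c.key for c in stage1],
        stage2_ids=[c.key for c in stage2],
        stage3_ids=[c.key for c in stage3],
        stage4_ids=None if stage4 is None else [c.key for c in stage4],
        ranked=ranked,
        adme_flags=adme_flags,
    )


# -- potency arithmetic ------------------------------------------------------


def lipe(pic50: float, clogp: float) -> float:
    """Lipophilic efficiency: pIC50 - cLogP."""
    if not (math.isfinite(pic50) and math.isfinite(clogp)):
        raise ValueError("lipe requires finite inputs")
    return pic50 - clogp


def pic50_from_ic50(ic50_nm: float) -> float:
    """pIC50 = -log10(IC50 in mol/L) = 9 - log10(IC50 in nM)."""
    if ic50_nm <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nm}")
    return 9.0 - math.log10(ic50_nm)


def ic50_from_pic50(pic50: float) -> float:
    """Inverse of :func:`pic50_from_ic50`, returning nM."""
    return 10.0 ** (9.0 - pic50)


# -- scorer registry ---------------------------------------------------------

#: name -> (endpoint, units, callable SMILES -> float)
_SCORERS: dict[str, tuple[str, str, Callable[[str], float]]] = {}


def register_scorer(
    name: str, endpoint: str, units: str, fn: Callable[[str], float]
) -> None:
    """Register a scorer plug-in mapping a product SMILES to a value.

    External models (structure-based potency scoring, proprietary ADME
    models) enter the pipeline only through this contract.
    """
    if name in _SCORERS:
        raise RegistrationError(f"scorer {name!r} already registered")
    _SCORERS[name] = (endpoint, units, fn)


def unregister_scorer(name: str) -> None:
    _SCORERS.pop(name, None)


def get_scorer(name: str) -> Callable[[str], float]:
    if name not in _SCORERS:
        _ensure_builtins()
    if name not in _SCORERS:
        raise RegistrationError(f"no scorer named {name!r}")
    return _SCORERS[name][2]


def list_scorers() -> dict:
    _ensure_builtins()
    return {k: {"endpoint": v[0], "units": v[1]} for k, v in _SCORERS.items()}


def _ensure_builtins() -> None:
    if "potency:synthetic" in _SCORERS:
        return
    from . import toyscore

    register_scorer(
        "potency:synthetic", "pic50", "log10(mol/L)", toyscore.synthetic_potency
    )
    register_scorer("yield:synthetic", "yield", "fraction", toyscore.synthetic_yield)
    register_scorer("adme:toy-logp", "logd", "unitless", toyscore.toy_logd)
    register_scorer("adme:toy-lysa", "lysa", "ug/mL", toyscore.toy_lysa)
    register_scorer("adme:toy-pgp", "pgp_ratio", "unitless", toyscore.toy_pgp)
    register_scorer("adme:toy-pampa", "pampa", "1e-6 cm/s", toyscore.toy_pampa)
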