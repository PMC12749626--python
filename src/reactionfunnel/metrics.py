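"""Evaluation metrics for reaction yield and binary-outcome prediction."""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError


def _paired(pred, true) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    t = np.asarray(true, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError(f"prediction/truth shape mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    return p, t


def mae(pred: Sequence[float], true: Sequence[float]) -> float:
    """Mean absolute error on the native (fraction) yield scale."""
    p, t = _paired(pred, true)
    return float(np.abs(p - t).mean())


def pearson(pred: Sequence[float], true: Sequence[float]) -> float:
    """Product-moment correlation; raises on constant input instead of NaN."""
    p, t = _paired(pred, true)
    if p.size < 2:
        raise ValueError("pearson requires at least two pairs")
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        raise ValidationError("pearson undefined for constant input")
    pc = p - p.mean()
    tc = t - t.mean()
    return float((pc * tc).sum() / math.sqrt((pc**2).sum() * (tc**2).sum()))


def binary_metrics(
    pred_yield: Sequence[float],
    true_yield: Sequence[float],
    threshold: float = 0.05,
) -> dict:
    """Accuracy and precision (in %) of thresholded yield classification.

    Both sides are labeled positive when yield >= threshold. With zero
    predicted positives, precision is reported as None (undefined) rather
    than 0.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    p, t = _paired(pred_yield, true_yield)
    pl = p >= threshold
    tl = t >= threshold
    tp = int(np.sum(pl & tl))
    fp = int(np.sum(pl & ~tl))
    tn = int(np.sum(~pl & ~tl))
    fn = int(np.sum(~pl & tl))
    accuracy = 100.0 * (tp + tn) / p.size
    precision = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else None
    return {
        "accuracy": accuracy,
        "precision": precision,
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "n": int(p.size),
    }


@dataclasses.dataclass
class EvalReport:
    """Cross-validation means and spreads for a set of named metrics."""

    means: dict
    sds: dict
    fold_values: dict
    n_folds: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def crossval_report(per_fold_metrics: Sequence[Mapping[str, float]]) -> EvalReport:
    """Aggregate per-fold metric dicts into means and sample (n-1) SDs.

    With a single fold the SD is reported as None. Metric values of None
    (e.g. undefined precision) are excluded from that metric's aggregation.
    """
    if len(per_fold_metrics) == 0:
        raise ValueError("no folds to aggregate")
    names: list[str] = []
    for fold in per_fold_metrics:
        for k in fold:
            if k not in names:
                names.append(k)
    fold_values = {
        name: [fold.get(name) for fold in per_fold_metrics if fold.get(name) is not None]
        for name in names
    }
    means = {}
    sds = {}
    for name, vals in fold_values.items():
        arr = np.asarray(vals, dtype=float)
        means[name] = float(arr.mean()) if arr.size else None
        sds[name] = float(arr.std(ddof=1)) if arr.size > 1 else None
    return EvalReport(
        means=means, sds=sds, fold_values=fold_values, n_folds=len(per_fold_metrics)
    )
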