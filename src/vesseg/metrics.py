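"""Voxel-overlap metrics and cross-validation aggregation.

All four scores derive from the voxel confusion counts between a predicted
and a reference binary mask:

    Dice        = 2TP / (2TP + FP + FN)
    Accuracy    = (TP + TN) / (TP + TN + FP + FN)
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)

A metric whose denominator is zero (e.g. Dice when both masks are empty) is
reported as *undefined* (NaN) rather than silently coerced to 0 or 1; the
report records which metrics were undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "dice",
    "accuracy",
    "sensitivity",
    "specificity",
    "dice_overlap_crosscheck",
    "evaluate_masks",
    "aggregate_folds",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_binary(mask) -> np.ndarray:
    v = getattr(mask, "voxels", mask)
    v = np.asarray(v)
    if not np.all(np.isin(np.unique(v), (0, 1))):
        raise ValueError("masks must be binary")
    return v.astype(bool)


def confusion(pred, truth) -> ConfusionCounts:
    """Exact TP/TN/FP/FN voxel tallies between two binary masks."""
    p = _as_binary(pred)
    g = _as_binary(truth)
    if p.shape != g.shape:
        raise ValueError(f"grid mismatch: {p.shape} vs {g.shape}")
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def dice(counts: ConfusionCounts) -> float:
    return _ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn)


def accuracy(counts: ConfusionCounts) -> float:
    return _ratio(counts.tp + counts.tn, counts.total)


def sensitivity(counts: ConfusionCounts) -> float:
    return _ratio(counts.tp, counts.tp + counts.fn)


def specificity(counts: ConfusionCounts) -> float:
    return _ratio(counts.tn, counts.tn + counts.fp)


def dice_overlap_crosscheck(pred, truth) -> float:
    """Dice via the set-overlap form 2|P∩G|/(|P|+|G|).

    Mathematically identical to ``dice(confusion(pred, truth))``; kept as an
    independent route so the two can cross-validate each other.
    """
    p = _as_binary(pred)
    g = _as_binary(truth)
    if p.shape != g.shape:
        raise ValueError(f"grid mismatch: {p.shape} vs {g.shape}")
    den = int(p.sum()) + int(g.sum())
    return _ratio(2 * int(np.sum(p & g)), den)


_METRICS = {
    "dice": dice,
    "accuracy": accuracy,
    "sensitivity": sensitivity,
    "specificity": specificity,
}


@dataclass
class MetricsReport:
    dice: float
    accuracy: float
    sensitivity: float
    specificity: float
    undefined: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "dice": self.dice,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "undefined": list(self.undefined),
        }


def evaluate_masks(pred, truth) -> MetricsReport:
    """All four metrics from a predicted/reference mask pair."""
    c = confusion(pred, truth)
    vals = {k: fn(c) for k, fn in _METRICS.items()}
    undefined = [k for k, v in vals.items() if math.isnan(v)]
    return MetricsReport(**vals, undefined=undefined)


def aggregate_folds(per_fold: list) -> dict:
    """Mean ± sample (n-1) standard deviation per metric across CV folds.

    ``per_fold`` is a list of MetricsReport or plain metric dicts; undefined
    (NaN) fold values are excluded from that metric's aggregate and counted.
    """
    if len(per_fold) < 2:
        raise ValueError("fold aggregation needs at least 2 folds")
    rows = [r.as_dict() if isinstance(r, MetricsReport) else dict(r) for r in per_fold]
    out = {}
    for key in _METRICS:
        vals = np.array([r[key] for r in rows], dtype=float)
        ok = vals[~np.isnan(vals)]
        out[key] = {
            "mean": float(ok.mean()) if ok.size else math.nan,
            "std": float(ok.std(ddof=1)) if ok.size > 1 else math.nan,
            "n_folds": int(ok.size),
        }
    return out
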