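"""Evaluation measures: Dice overlap for segmentation, accuracy/precision/recall
for the normal-vs-anomalous classification.

The positive class is ``anomalous`` throughout, so recall = 1 means no
anomalous case was missed — the clinically critical direction, since a missed
anomaly is an under-diagnosis.  Zero-denominator rates return NaN (undefined),
never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeMismatchError

NORMAL = "normal"
ANOMALOUS = "anomalous"
_KNOWN = (NORMAL, ANOMALOUS)


@dataclass
class SegMetrics:
    """Per-case Dice scores for the two structures of interest."""

    dsc_aorta: float
    dsc_coronary: float


@dataclass
class ClfMetrics:
    accuracy: float
    precision: float
    recall: float


def dice(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice score 2|A∩B| / (|A|+|B|) between two binary masks.

    Both masks empty is perfect agreement on absence and scores 1.0.
    """
    pred = np.asarray(pred_mask).astype(bool)
    true = np.asarray(true_mask).astype(bool)
    if pred.shape != true.shape:
        raise ShapeMismatchError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    denom = int(pred.sum()) + int(true.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(pred, true).sum()) / denom


def segmentation_metrics(pred, true) -> SegMetrics:
    """Dice per class between predicted and true LabelVolume (or raw grids)."""
    p = getattr(pred, "data", pred)
    t = getattr(true, "data", true)
    return SegMetrics(
        dsc_aorta=dice(p == 1, t == 1),
        dsc_coronary=dice(p == 2, t == 2),
    )


def classification_report(pred_labels, true_labels) -> ClfMetrics:
    """Accuracy, precision and recall with ``anomalous`` as the positive class."""
    pred = list(pred_labels)
    true = list(true_labels)
    if len(pred) != len(true):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(true)} truths")
    for lab in pred + true:
        if lab not in _KNOWN:
            raise ValueError(f"unknown label {lab!r}; expected one of {_KNOWN}")
    tp = sum(1 for p, t in zip(pred, true) if p == ANOMALOUS and t == ANOMALOUS)
    fp = sum(1 for p, t in zip(pred, true) if p == ANOMALOUS and t == NORMAL)
    fn = sum(1 for p, t in zip(pred, true) if p == NORMAL and t == ANOMALOUS)
    correct = sum(1 for p, t in zip(pred, true) if p == t)
    n = len(true)
    accuracy = correct / n if n else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    return ClfMetrics(accuracy=accuracy, precision=precision, recall=recall)


def summarize_dsc(metrics: list[SegMetrics]) -> dict:
    """Mean ± sd and median of the per-case Dice scores, per class.

    sd is the population standard deviation (ddof=0), so a single case reports
    sd 0 rather than an undefined value.
    """
    if not metrics:
        raise ValueError("empty metrics list")
    out = {}
    for cls, attr in (("aorta", "dsc_aorta"), ("coronary", "dsc_coronary")):
        vals = np.array([getattr(m, attr) for m in metrics], dtype=float)
        out[cls] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=0)),
            "median": float(np.median(vals)),
        }
    return out
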