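"""Overlap-based evaluation measures for segmentation masks.

All measures operate on binary numpy arrays of identical shape (2D slices or
3D volumes).  The Dice coefficient, precision and recall follow the usual
set-overlap definitions; IoU (Jaccard) additionally drives region tracking
elsewhere in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvalReport",
    "dice",
    "precision_recall",
    "iou",
    "evaluate",
    "pooled_label_dice",
]


@dataclass
class EvalReport:
    """Pixel-count summary of a prediction/ground-truth comparison."""

    dice: float
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int


def _as_bool(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a.astype(bool), b.astype(bool)


def dice(pred, truth) -> float:
    """Dice coefficient 2|P∩G|/(|P|+|G|); 1 is perfect overlap, 0 is none."""
    p, g = _as_bool(pred, truth)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        warnings.warn("dice of two empty masks; returning 1.0")
        return 1.0
    return 2.0 * int(np.logical_and(p, g).sum()) / denom


def precision_recall(pred, truth) -> tuple[float, float]:
    """(precision, recall) = (|P∩G|/|P|, |P∩G|/|G|)."""
    p, g = _as_bool(pred, truth)
    inter = int(np.logical_and(p, g).sum())
    np_, ng = int(p.sum()), int(g.sum())
    if ng == 0:
        warnings.warn("empty ground truth; recall reported as 1")
        recall = 1.0
    else:
        recall = inter / ng
    if np_ == 0:
        warnings.warn("empty prediction; precision degenerate")
        precision = 1.0 if ng == 0 else 0.0
    else:
        precision = inter / np_
    return precision, recall


def iou(region_a, region_b) -> float:
    """Intersection over union of two binary regions."""
    a, b = _as_bool(region_a, region_b)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        warnings.warn("IoU of two empty regions; returning 0.0")
        return 0.0
    return int(np.logical_and(a, b).sum()) / union


def evaluate(pred, truth) -> EvalReport:
    """Full report (Dice, precision, recall and the raw counts)."""
    p, g = _as_bool(pred, truth)
    tp = int(np.logical_and(p, g).sum())
    fp = int(p.sum()) - tp
    fn = int(g.sum()) - tp
    d = 1.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    prec = 1.0 if (tp + fp) == 0 and fn == 0 else (tp / (tp + fp) if tp + fp else 0.0)
    rec = 1.0 if (tp + fn) == 0 else tp / (tp + fn)
    return EvalReport(dice=d, precision=prec, recall=rec, tp=tp, fp=fp, fn=fn)


def pooled_label_dice(pred_labels, truth_labels) -> float:
    """Dice pooled over all object labels of an instance segmentation.

    Per-label true positives are pixels carrying the same id in both volumes;
    pooling sums counts over labels before forming 2·TP/(|P|+|G|), so large
    and small cells weigh by their area.  Background (0) is excluded.
    """
    p = np.asarray(pred_labels)
    g = np.asarray(truth_labels)
    if p.shape != g.shape:
        raise ValueError("shape mismatch")
    ids = np.union1d(np.unique(p[p > 0]), np.unique(g[g > 0]))
    tp = sum(int(np.logical_and(p == i, g == i).sum()) for i in ids)
    denom = int((p > 0).sum()) + int((g > 0).sum())
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom
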