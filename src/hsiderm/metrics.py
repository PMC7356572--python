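"""Segmentation and classification evaluation metrics.

Overlap metrics (Dice, Jaccard) compare a segmented mask against the
ground truth via confusion counts; classifier metrics cover sensitivity,
specificity, accuracy and ROC AUC.  AUC is the Mann-Whitney concordance
probability (ties credited 1/2), which equals the trapezoidal area under
the ROC curve.

Ratios whose denominator is zero (e.g. specificity when no negatives
exist) are reported as ``math.nan`` — an explicit not-available marker,
never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .hsio import BinaryMask

__all__ = [
    "ConfusionCounts",
    "confusion",
    "dice",
    "jaccard",
    "sens_spec_acc",
    "roc_auc",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion(si: BinaryMask, gt: BinaryMask) -> ConfusionCounts:
    """Confusion counts of a segmented image against the ground truth."""
    if si.shape != gt.shape:
        raise ValueError("masks must share shape")
    s = si.values
    g = gt.values
    return ConfusionCounts(
        TP=int(np.sum(s & g)),
        FP=int(np.sum(s & ~g)),
        FN=int(np.sum(~s & g)),
        TN=int(np.sum(~s & ~g)),
    )


def dice(c: ConfusionCounts) -> float:
    """Dice = 2TP / (2TP + FP + FN)."""
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        raise ValueError("Dice undefined: both masks empty")
    return 2 * c.TP / denom


def jaccard(c: ConfusionCounts) -> float:
    """Jaccard = TP / (TP + FP + FN)."""
    denom = c.TP + c.FP + c.FN
    if denom == 0:
        raise ValueError("Jaccard undefined: both masks empty")
    return c.TP / denom


def sens_spec_acc(c: ConfusionCounts) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy); undefined terms are NaN.

    With no true negatives and no false positives — the case when every
    pixel under evaluation belongs to one class — accuracy reduces to
    sensitivity and specificity is not available.
    """
    if c.total == 0:
        raise ValueError("no counts")
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else math.nan
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) > 0 else math.nan
    acc = (c.TP + c.TN) / c.total
    return sens, spec, acc


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney concordance probability.

    P(score_pos > score_neg) + 0.5 * P(score_pos == score_neg), computed
    from midranks; identical to the trapezoidal area under the ROC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores)  # midranks handle ties with half credit
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
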