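"""Segmentation evaluation: mDice, mIoU, sensitivity, specificity,
S-measure and MAE.

Count-based metrics work on binarized masks through a per-image pixel
confusion (TP/FP/TN/FN); the S-measure and MAE consume the raw
probability map.  All set-level scores are per-image means, matching the
way polyp benchmarks report them.

The S-measure is the structure measure of Fan et al. (2017):
``S = α·S_O + (1−α)·S_R`` with α = 0.5, combining an object-aware term
(foreground/background mean–dispersion similarity) and a region-aware
term (SSIM-style comparison on the four quadrants around the ground
truth's centroid, area-weighted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "dice_coefficient",
    "iou",
    "sensitivity",
    "specificity",
    "s_measure",
    "mae",
    "evaluate_set",
]

_EPS = np.finfo(np.float64).eps


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of one predicted/reference mask pair."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Per-image means of the six measures over an evaluation set."""

    mdice: float
    miou: float
    sens: float
    spe: float
    sm: float
    mae: float
    n_images: int


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be strictly binary (0/1)")
    return arr.astype(bool)


def confusion(pred_mask, gt_mask) -> ConfusionCounts:
    """Four-way pixel classification of a binary pred/gt pair."""
    pred = _check_binary(pred_mask, "pred_mask")
    gt = _check_binary(gt_mask, "gt_mask")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def dice_coefficient(counts: ConfusionCounts) -> float:
    """2·TP / (2·TP + FP + FN); 1 when both masks are empty."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return 2.0 * counts.tp / denom


def iou(counts: ConfusionCounts) -> float:
    """TP / (TP + FP + FN); 1 when both masks are empty."""
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return counts.tp / denom


def sensitivity(counts: ConfusionCounts) -> float:
    """TP / (TP + FN); 1 for an empty ground truth (nothing to miss)."""
    denom = counts.tp + counts.fn
    if denom == 0:
        return 1.0
    return counts.tp / denom


def specificity(counts: ConfusionCounts) -> float:
    """TN / (TN + FP); 1 for an all-foreground ground truth."""
    denom = counts.tn + counts.fp
    if denom == 0:
        return 1.0
    return counts.tn / denom


def mae(pred, gt) -> float:
    """Mean absolute pixel difference between probability map and mask."""
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    return float(np.abs(pred - gt).mean())


# ------------------------------------------------------------ S-measure

def _object_score(x: np.ndarray) -> float:
    """Mean–dispersion similarity of the masked prediction values."""
    mu = x.mean()
    sigma = x.std(ddof=1) if x.size > 1 else 0.0
    return 2.0 * mu / (mu * mu + 1.0 + sigma + _EPS)


def _s_object(pred: np.ndarray, gt: np.ndarray) -> float:
    fg = pred[gt]
    bg = 1.0 - pred[~gt]
    u = gt.mean()
    o_fg = _object_score(fg) if fg.size else 0.0
    o_bg = _object_score(bg) if bg.size else 0.0
    return u * o_fg + (1.0 - u) * o_bg


def _centroid(gt: np.ndarray) -> tuple[int, int]:
    h, w = gt.shape
    if not gt.any():
        return h // 2, w // 2
    rows, cols = np.nonzero(gt)
    return int(np.round(rows.mean())), int(np.round(cols.mean()))


def _ssim_region(p: np.ndarray, g: np.ndarray) -> float:
    """SSIM-style structural comparison of one quadrant."""
    n = p.size
    if n == 0:
        return 1.0
    x, y = p.mean(), g.mean()
    if n > 1:
        sx = ((p - x) ** 2).sum() / (n - 1)
        sy = ((g - y) ** 2).sum() / (n - 1)
        sxy = ((p - x) * (g - y)).sum() / (n - 1)
    else:
        sx = sy = sxy = 0.0
    alpha = 4.0 * x * y * sxy
    beta = (x * x + y * y) * (sx + sy)
    if alpha != 0.0:
        return float(alpha / (beta + _EPS))
    if beta == 0.0:
        return 1.0
    return 0.0


def _s_region(pred: np.ndarray, gt: np.ndarray) -> float:
    ci, cj = _centroid(gt)
    h, w = gt.shape
    # split at the centroid; weights proportional to quadrant area
    rows = (slice(0, ci + 1), slice(ci + 1, h))
    cols = (slice(0, cj + 1), slice(cj + 1, w))
    score = 0.0
    total = h * w
    for rs in rows:
        for cs in cols:
            gq = gt[rs, cs]
            weight = gq.size / total
            score += weight * _ssim_region(pred[rs, cs], gq.astype(np.float64))
    return score


def s_measure(pred, gt, alpha: float = 0.5) -> float:
    """Structure measure ``α·S_O + (1−α)·S_R``, clamped to [0, 1].

    Degenerate ground truths follow the reference conventions: for an
    empty gt the score is ``1 − mean(pred)``, for an all-foreground gt it
    is ``mean(pred)``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    pred = np.asarray(pred, dtype=np.float64)
    gt = _check_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    y = gt.mean()
    if y == 0.0:
        return float(np.clip(1.0 - pred.mean(), 0.0, 1.0))
    if y == 1.0:
        return float(np.clip(pred.mean(), 0.0, 1.0))
    score = alpha * _s_object(pred, gt) + (1.0 - alpha) * _s_region(pred, gt)
    return float(np.clip(score, 0.0, 1.0))


def evaluate_set(pairs, threshold: float = 0.5) -> MetricsReport:
    """Six-metric report over ``(pred, gt)`` pairs.

    Predictions are binarized at ``threshold`` for the count-based
    metrics; S-measure and MAE use the raw probabilities.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_set needs at least one (pred, gt) pair")
    dices, ious, senss, spes, sms, maes = [], [], [], [], [], []
    for pred, gt in pairs:
        pred = np.asarray(pred, dtype=np.float64)
        gt_b = _check_binary(gt, "gt").astype(np.uint8)
        pred_b = (pred >= threshold).astype(np.uint8)
        counts = confusion(pred_b, gt_b)
        dices.append(dice_coefficient(counts))
        ious.append(iou(counts))
        senss.append(sensitivity(counts))
        spes.append(specificity(counts))
        sms.append(s_measure(pred, gt_b))
        maes.append(mae(pred, gt_b))
    return MetricsReport(
        mdice=float(np.mean(dices)),
        miou=float(np.mean(ious)),
        sens=float(np.mean(senss)),
        spe=float(np.mean(spes)),
        sm=float(np.mean(sms)),
        mae=float(np.mean(maes)),
        n_images=len(pairs),
    )
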