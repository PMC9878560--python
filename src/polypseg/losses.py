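"""Compound training objective: Dice loss + focal loss.

Dice loss measures overlap between the predicted probability map and the
binary ground truth,

    L_dice = 1 − (2·Σ p·t + s) / (Σ p + Σ t + s),

computed per image and averaged over the batch; the smoothing constant
``s`` keeps empty masks safe.  Focal loss is the class-balanced,
difficulty-weighted cross entropy

    L_focal = mean_pixels[ −α_t · (1 − p_t)^γ · log p_t ],

with ``p_t = p`` and ``α_t = α`` on polyp pixels, ``p_t = 1 − p`` and
``α_t = 1 − α`` on background.  The total objective is their (by default
unweighted) sum.  Both losses accept :class:`~polypseg.autodiff.Tensor`
inputs and are differentiable; plain numpy arrays are wrapped as
constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = ["LossConfig", "dice_loss", "focal_loss", "total_loss"]

_CLAMP_EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    dice_smooth: float = 1.0
    dice_weight: float = 1.0
    focal_weight: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.focal_alpha <= 1.0:
            raise ValueError("focal_alpha must lie in [0, 1]")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")
        if self.dice_smooth < 0:
            raise ValueError("dice_smooth must be >= 0")


def _as_batched(t) -> Tensor:
    """Wrap input and normalise to N×(C·H·W) layout-agnostic 4-d/2-d use."""
    if not isinstance(t, Tensor):
        t = Tensor(np.asarray(t, dtype=np.float32))
    if t.ndim < 2:
        t = t.reshape(1, -1)
    return t


def dice_loss(pred, target, smooth: float = 1.0) -> Tensor:
    """Soft Dice loss in [0, 1], per image, averaged over the batch.

    With ``smooth == 0`` an empty-prediction/empty-target pair is defined
    as loss 0 (perfect agreement); any ``smooth > 0`` already yields 0
    there.
    """
    pred, target = _as_batched(pred), _as_batched(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    n = pred.shape[0]
    p = pred.reshape(n, -1)
    t = target.reshape(n, -1)
    inter = (p * t).sum(axis=1)
    denom = p.sum(axis=1) + t.sum(axis=1)
    # Degenerate samples (Σp + Σt + smooth == 0) get loss 0 by adding a
    # unit constant to numerator and denominator there; such samples are
    # all-zero, so no gradient is lost.
    degenerate = (denom.data + smooth == 0).astype(np.float32)
    loss = 1.0 - (inter * 2.0 + smooth + Tensor(degenerate)) / (
        denom + smooth + Tensor(degenerate)
    )
    return loss.mean()


def focal_loss(pred, target, cfg: LossConfig = LossConfig()) -> Tensor:
    """Two-sided focal loss, mean over all pixels."""
    pred, target = _as_batched(pred), _as_batched(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = pred.clip(_CLAMP_EPS, 1.0 - _CLAMP_EPS)
    t = target
    p_t = p * t + (1.0 - p) * (1.0 - t)
    alpha_t = cfg.focal_alpha * t + (1.0 - cfg.focal_alpha) * (1.0 - t)
    focal = -1.0 * alpha_t * (1.0 - p_t) ** cfg.focal_gamma * p_t.log()
    return focal.mean()


def total_loss(pred, target, cfg: LossConfig = LossConfig()) -> Tensor:
    """Weighted sum of Dice and focal losses (default weights 1, 1)."""
    return (
        cfg.dice_weight * dice_loss(pred, target, smooth=cfg.dice_smooth)
        + cfg.focal_weight * focal_loss(pred, target, cfg)
    )
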