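"""Focal loss for the heavily class-imbalanced contact labels.

Per residue pair:

    FL(p_t) = -alpha_t * (1 - p_t)^gamma * log(p_t)

with p_t = p_ij for a contact (y = 1) and 1 - p_ij otherwise, and
alpha_t = alpha for contacts, 1 - alpha otherwise.  Masked (unobserved)
pairs are excluded; the reduction is the mean over unmasked pairs, so the
loss scale does not depend on protein length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FocalLossConfig:
    alpha: float = 0.25
    gamma: float = 1.5

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


def _pt_at(p, y, cfg):
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError("probability and label arrays must share a shape")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    pt = np.where(y == 1, p, 1.0 - p)
    at = np.where(y == 1, cfg.alpha, 1.0 - cfg.alpha)
    return pt, at


def focal_loss(p: np.ndarray, y: np.ndarray, mask: np.ndarray | None = None,
               cfg: FocalLossConfig = FocalLossConfig()) -> float:
    """Mean focal loss over unmasked pairs (gamma=0 gives weighted BCE)."""
    pt, at = _pt_at(p, y, cfg)
    fl = -at * (1.0 - pt) ** cfg.gamma * np.log(pt)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("all pairs are masked; loss undefined")
        fl = fl[mask]
    return float(fl.mean())


def focal_loss_grad(p: np.ndarray, y: np.ndarray,
                    mask: np.ndarray | None = None,
                    cfg: FocalLossConfig = FocalLossConfig()) -> np.ndarray:
    """d(mean focal loss)/dp, zero at masked entries."""
    pt, at = _pt_at(p, y, cfg)
    g = cfg.gamma
    one_m = 1.0 - pt
    # d FL / d p_t
    dfl_dpt = -at * (-g * one_m ** (g - 1) * np.log(pt) + one_m ** g / pt) \
        if g > 0 else -at / pt
    sign = np.where(np.asarray(y) == 1, 1.0, -1.0)
    grad = dfl_dpt * sign
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        grad = np.where(mask, grad, 0.0)
        n = mask.sum()
    else:
        n = grad.size
    if n == 0:
        raise ValueError("all pairs are masked; loss undefined")
    return grad / n
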