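"""Training objectives: soft Dice segmentation loss, MSE regression loss,
and their λ-weighted combination L_intg = λ·L_seg + (1−λ)·L_reg.

Dice is computed per image and averaged over the batch; a smoothing
constant ε in numerator and denominator keeps the empty-mask case finite.
Analytic gradients (w.r.t. the network outputs) are provided for the
NumPy training loop.
"""

from __future__ import annotations

import numpy as np

DICE_EPS = 1e-6


def _check_pair(s_pred, s_gt):
    s_pred = np.asarray(s_pred, dtype=np.float64)
    s_gt = np.asarray(s_gt, dtype=np.float64)
    if s_pred.shape != s_gt.shape:
        raise ValueError(f"shape mismatch: {s_pred.shape} vs {s_gt.shape}")
    return s_pred, s_gt


def dice_loss(s_pred: np.ndarray, s_gt: np.ndarray, eps: float = DICE_EPS) -> float:
    """1 − 2(|S_pred ∩ S_gt| + ε) / (|S_pred| + |S_gt| + ε) for one pair.

    ``s_pred`` may be a soft probability map; the intersection is the sum of
    the elementwise product.  With ``eps=0`` and both maps empty the loss is
    undefined and a ValueError is raised.
    """
    s_pred, s_gt = _check_pair(s_pred, s_gt)
    inter = float((s_pred * s_gt).sum())
    denom = float(s_pred.sum() + s_gt.sum())
    if denom + eps == 0:
        raise ValueError("Dice undefined: both maps empty and eps = 0")
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def dice_loss_batch(s_pred: np.ndarray, s_gt: np.ndarray,
                    eps: float = DICE_EPS) -> float:
    """Per-image Dice loss averaged over a (N, H, W) batch."""
    s_pred, s_gt = _check_pair(s_pred, s_gt)
    inter = (s_pred * s_gt).sum(axis=(1, 2))
    denom = s_pred.sum(axis=(1, 2)) + s_gt.sum(axis=(1, 2))
    return float(np.mean(1.0 - (2.0 * inter + eps) / (denom + eps)))


def dice_loss_grad(s_pred: np.ndarray, s_gt: np.ndarray,
                   eps: float = DICE_EPS) -> np.ndarray:
    """d(dice_loss_batch)/d s_pred, shape (N, H, W)."""
    s_pred, s_gt = _check_pair(s_pred, s_gt)
    n = s_pred.shape[0]
    inter = (s_pred * s_gt).sum(axis=(1, 2))[:, None, None]
    denom = (s_pred.sum(axis=(1, 2)) + s_gt.sum(axis=(1, 2)))[:, None, None] + eps
    grad = -2.0 * s_gt / denom + (2.0 * inter + eps) / denom ** 2
    return grad / n


def mse_loss(bmd_pred, bmd_gt) -> float:
    """(1/n) Σ (BMD_pred − BMD_gt)², in (g/cm²)²."""
    p = np.asarray(bmd_pred, dtype=np.float64).ravel()
    g = np.asarray(bmd_gt, dtype=np.float64).ravel()
    if p.size == 0:
        raise ValueError("mse_loss needs at least one pair")
    if p.size != g.size:
        raise ValueError("prediction/ground-truth length mismatch")
    return float(np.mean((p - g) ** 2))


def mse_loss_grad(bmd_pred, bmd_gt) -> np.ndarray:
    p = np.asarray(bmd_pred, dtype=np.float64).ravel()
    g = np.asarray(bmd_gt, dtype=np.float64).ravel()
    return 2.0 * (p - g) / p.size


def combined_loss(l_seg: float, l_reg: float, lam: float) -> float:
    """λ·L_seg + (1−λ)·L_reg with λ ∈ [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    return lam * l_seg + (1.0 - lam) * l_reg
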