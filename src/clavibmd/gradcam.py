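"""Regression Grad-CAM: gradient-weighted activation heatmaps for the
scalar BMD output, thresholded at a fraction of their maximum and scored
for overlap with the ground-truth clavicle mask.

The channel weights are spatial means of the exact backpropagated
gradients of BMD_pred with respect to the final encoder (bottleneck)
feature maps; the heatmap is the ReLU of the weighted channel sum,
bilinearly up-sampled to the input resolution.  A case "overlaps" when the
set of pixels above 50 % of the heatmap maximum shares at least one pixel
with the clavicle mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize


@dataclass
class GradCamArtifacts:
    A: np.ndarray              # (K, U, V) feature maps
    grads: np.ndarray          # (K, U, V) dBMD_pred/dA
    alpha: np.ndarray          # (K,) channel weights
    heatmap_low: np.ndarray    # (U, V), nonnegative
    heatmap_full: np.ndarray   # input-size map
    highlighted: np.ndarray | None = None   # binary input-size map
    overlap: bool | None = None
    overlap_area_fraction: float | None = None


def channel_weights(grads: np.ndarray) -> np.ndarray:
    """α_k = (1/UV) Σ_uv ∂BMD_pred/∂A^k_uv — spatial mean per channel."""
    grads = np.asarray(grads, dtype=np.float64)
    if grads.ndim != 3 or grads.shape[1] == 0 or grads.shape[2] == 0:
        raise ValueError("grads must be a non-empty (K, U, V) stack")
    return grads.mean(axis=(1, 2))


def heatmap(A: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """L_Grad = ReLU(Σ_k α_k A^k)."""
    A = np.asarray(A, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64).ravel()
    if A.ndim != 3 or A.shape[0] != alpha.size:
        raise ValueError("alpha length must match the number of feature maps")
    return np.maximum((alpha[:, None, None] * A).sum(axis=0), 0.0)


def threshold_and_overlap(heatmap_full: np.ndarray, mask: np.ndarray,
                          frac: float = 0.5) -> tuple[np.ndarray, bool]:
    """Highlight pixels strictly above ``frac`` of the heatmap maximum and
    test for ≥ 1 shared pixel with the mask.

    An all-zero heatmap highlights nothing (overlap False).  An exactly
    uniform positive heatmap would highlight nothing under the strict
    rule, so it is special-cased to highlight every pixel.
    """
    hm = np.asarray(heatmap_full, dtype=np.float64)
    mask = np.asarray(mask)
    if hm.shape != mask.shape:
        raise ValueError(f"shape mismatch: {hm.shape} vs {mask.shape}")
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    peak = hm.max()
    if peak <= 0:
        highlighted = np.zeros(hm.shape, dtype=bool)
    elif hm.min() == peak:
        highlighted = np.ones(hm.shape, dtype=bool)
    else:
        highlighted = hm > frac * peak
    overlap = bool(np.any(highlighted & (mask > 0)))
    return highlighted, overlap


def overlap_area_fraction(highlighted: np.ndarray, mask: np.ndarray) -> float:
    """Stricter variant: fraction of highlighted pixels inside the mask."""
    highlighted = np.asarray(highlighted, dtype=bool)
    n_high = int(highlighted.sum())
    if n_high == 0:
        return 0.0
    return float((highlighted & (np.asarray(mask) > 0)).sum()) / n_high


def compute_gradcam(handle, image: np.ndarray, mask: np.ndarray | None = None,
                    frac: float = 0.5) -> GradCamArtifacts:
    """Full Grad-CAM pipeline for one image on a built network.

    ``handle`` needs ``encoder_features`` and ``feature_gradients`` (any
    object exposing them works, which keeps the construction testable on
    hand-built toy networks).  When ``mask`` is given the thresholded
    overlap flag is filled in.
    """
    A_raw = handle.encoder_features(image)
    grads = np.asarray(handle.feature_gradients(A_raw), dtype=np.float64)
    A = np.asarray(A_raw, dtype=np.float64)
    if grads.shape != A.shape:
        raise ValueError("gradient stack must match feature stack shape")
    alpha = channel_weights(grads)
    hm_low = heatmap(A, alpha)
    size = np.asarray(image).shape
    hm_full = resize(hm_low, size, order=1, preserve_range=True,
                     anti_aliasing=False)
    hm_full = np.maximum(hm_full, 0.0)
    art = GradCamArtifacts(A=A, grads=grads, alpha=alpha,
                           heatmap_low=hm_low, heatmap_full=hm_full)
    if mask is not None:
        art.highlighted, art.overlap = threshold_and_overlap(hm_full, mask, frac)
        art.overlap_area_fraction = overlap_area_fraction(art.highlighted, mask)
    return art


def overlap_rate(flags) -> float:
    """Fraction of cases whose heatmap overlapped the clavicle."""
    flags = list(flags)
    if not flags:
        raise ValueError("overlap_rate needs at least one case")
    return float(sum(bool(f) for f in flags)) / len(flags)
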