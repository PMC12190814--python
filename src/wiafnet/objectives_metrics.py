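"""Segmentation objectives and evaluation metrics.

Training optimizes a weighted sum of soft Dice loss and cross-entropy;
evaluation reports the Dice similarity coefficient and the 95th-percentile
Hausdorff surface distance (HD95) on the three nested tumor regions used by
the BraTS labeling convention:

* ET (enhancing tumor)            = label {4}
* TC (tumor core)                 = labels {1, 4}
* WT (whole tumor)                = labels {1, 2, 4}

with label 1 = necrotic/non-enhancing core (NCR/NET) and label 2 = edema (ED).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "LossWeights",
    "RegionMasks",
    "dice_loss",
    "ce_loss",
    "combined_loss",
    "dice_score",
    "hd95",
    "brats_regions",
    "BRATS_LABELS",
]

BRATS_LABELS = (0, 1, 2, 4)


@dataclass(frozen=True)
class LossWeights:
    """Weights of the compound loss: lambda1 * Dice + lambda2 * CE."""

    lambda1: float = 1.0
    lambda2: float = 1.0
    eps: float = 1e-5

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0 or self.lambda1 + self.lambda2 <= 0:
            raise ValueError("loss weights must be nonnegative, not both zero")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class RegionMasks:
    """Nested binary evaluation regions ET ⊆ TC ⊆ WT."""

    ET: np.ndarray
    TC: np.ndarray
    WT: np.ndarray

    def __post_init__(self):
        for name in ("ET", "TC", "WT"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if self.ET.shape != self.TC.shape or self.TC.shape != self.WT.shape:
            raise ValueError("region masks must share a shape")
        if np.any(self.ET & ~self.TC) or np.any(self.TC & ~self.WT):
            raise ValueError("regions must nest: ET ⊆ TC ⊆ WT")

    def as_dict(self):
        return {"ET": self.ET, "TC": self.TC, "WT": self.WT}


# ---------------------------------------------------------------------------
# losses (NumPy reference forms; the autodiff training loss mirrors these)
# ---------------------------------------------------------------------------

def _foreground_classes(pred: np.ndarray, target: np.ndarray):
    """Yield (p_k, y_k) per foreground class; a plain mask is one class."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    if pred.ndim >= 4 and pred.shape[0] > 1:
        # class-stacked (K, ...) volumes: skip class 0 (background)
        for k in range(1, pred.shape[0]):
            yield pred[k], target[k]
    else:
        yield pred.squeeze(), target.squeeze()


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1e-5) -> float:
    """Soft Dice loss, averaged over foreground classes.

    ``1 - (2 sum(y p) + eps) / (sum(y) + sum(p) + eps)`` per class; `pred`
    holds per-class probabilities, `target` the matching one-hot labels.
    """
    losses = []
    for p, y in _foreground_classes(pred, target):
        inter = float((y * p).sum())
        denom = float(y.sum() + p.sum())
        losses.append(1.0 - (2.0 * inter + eps) / (denom + eps))
    return float(np.mean(losses))


def ce_loss(pred: np.ndarray, target: np.ndarray,
            clamp: float = 1e-12) -> float:
    """Mean voxelwise cross-entropy.

    Categorical over the leading class axis when present; the binary form
    ``-mean[y ln p + (1-y) ln(1-p)]`` is used for a single-probability input.
    """
    pred = np.clip(np.asarray(pred, dtype=np.float64), clamp, 1.0 - clamp)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("shape mismatch")
    if pred.ndim >= 4 and pred.shape[0] > 1:
        return float(-(target * np.log(pred)).sum(axis=0).mean())
    return float(-(target * np.log(pred)
                   + (1.0 - target) * np.log(1.0 - pred)).mean())


def combined_loss(pred: np.ndarray, target: np.ndarray,
                  weights: LossWeights | None = None) -> float:
    w = weights or LossWeights()
    return (w.lambda1 * dice_loss(pred, target, w.eps)
            + w.lambda2 * ce_loss(pred, target))


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

def dice_score(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Hard Dice coefficient 2|A∩B|/(|A|+|B|); two empty masks score 1."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(gt_mask, dtype=bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates of boundary voxels (mask minus its erosion)."""
    eroded = ndimage.binary_erosion(mask, border_value=0)
    return np.argwhere(mask & ~eroded)


def hd95(pred_mask: np.ndarray, gt_mask: np.ndarray,
         spacing=(1.0, 1.0, 1.0), percentile_mode: str = "pooled") -> float:
    """95th-percentile symmetric surface distance in mm.

    Distances between boundary voxels of the two masks are spacing-scaled;
    the default pools both directed distance sets before taking the 95th
    percentile (``percentile_mode="max_directed"`` takes the max of the two
    directed percentiles instead).  An empty mask on either side returns the
    volume diagonal as a sentinel.
    """
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(gt_mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=np.float64)
    if not a.any() or not b.any():
        return float(np.linalg.norm(np.asarray(a.shape) * spacing))
    sa = _surface_voxels(a) * spacing
    sb = _surface_voxels(b) * spacing
    d_ab = cKDTree(sb).query(sa, k=1)[0]
    d_ba = cKDTree(sa).query(sb, k=1)[0]
    if percentile_mode == "pooled":
        return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))
    if percentile_mode == "max_directed":
        return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))
    raise ValueError(f"unknown percentile_mode {percentile_mode!r}")


def brats_regions(labelmap: np.ndarray) -> RegionMasks:
    """Compose the nested ET/TC/WT evaluation regions from a BraTS labelmap."""
    lab = np.asarray(labelmap)
    unknown = set(np.unique(lab)) - set(BRATS_LABELS)
    if unknown:
        raise ValueError(f"unknown label values {sorted(unknown)}")
    return RegionMasks(ET=lab == 4,
                       TC=(lab == 1) | (lab == 4),
                       WT=(lab == 1) | (lab == 2) | (lab == 4))
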