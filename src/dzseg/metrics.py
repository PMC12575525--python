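"""Segmentation quality metrics: per-class IoU/Dice and boundary distances.

Conventions fixed here and used everywhere in the package:

* IoU = |P∩G| / |P∪G|, Dice = 2|P∩G| / (|P| + |G|); when a class is absent
  from both prediction and ground truth, both are defined as 1.0 (degenerate
  exact agreement).
* "Mean" IoU/Dice is the unweighted arithmetic mean over the two classes
  (dissection zone and no-go zone).
* Boundary pixels of a class are its pixels with at least one 4-neighbour
  outside the class or outside the image (inner boundary).
* ASSD = 0.5 * (mean_{a in A} d(a, B) + mean_{b in B} d(b, A)) and
  HD = max(max_{a in A} d(a, B), max_{b in B} d(b, A)) over Euclidean
  distances between pixel centers of the two boundary sets.  If exactly one
  boundary is empty, both distances fall back to the image diagonal as a
  finite sentinel; if both are empty the masks agree degenerately and the
  distances are 0.
* Dataset-level metrics are the mean over images of per-image metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

__all__ = [
    "MetricsReport", "iou_dice", "mean_over_classes", "boundary_pixels",
    "assd_hd", "evaluate_pair", "aggregate_reports",
]


@dataclass
class MetricsReport:
    """Per-class and mean overlap metrics plus boundary distances (pixels)."""

    iou_per_class: dict[int, float]
    dice_per_class: dict[int, float]
    mean_iou: float
    mean_dice: float
    assd: float
    hd: float

    def to_dict(self) -> dict:
        return {
            "iou_per_class": {str(k): v for k, v in self.iou_per_class.items()},
            "dice_per_class": {str(k): v for k, v in self.dice_per_class.items()},
            "mean_iou": self.mean_iou,
            "mean_dice": self.mean_dice,
            "assd": self.assd,
            "hd": self.hd,
        }


def _check_shapes(pred: np.ndarray, gt: np.ndarray) -> None:
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: pred {pred.shape} vs gt {gt.shape}")


def iou_dice(pred: np.ndarray, gt: np.ndarray, cls: int) -> tuple[float, float]:
    """Intersection-over-union and Dice of one class."""
    _check_shapes(pred, gt)
    p = pred == cls
    g = gt == cls
    inter = np.logical_and(p, g).sum()
    psum, gsum = p.sum(), g.sum()
    union = psum + gsum - inter
    if union == 0:
        return 1.0, 1.0
    iou = inter / union
    dice = 2.0 * inter / (psum + gsum)
    return float(iou), float(dice)


def mean_over_classes(per_class: dict[int, float],
                      classes: tuple[int, ...] = (0, 1)) -> float:
    """Unweighted mean of a per-class metric over the given classes."""
    missing = [c for c in classes if c not in per_class]
    if missing:
        raise ValueError(f"missing per-class values for classes {missing}")
    return float(np.mean([per_class[c] for c in classes]))


def boundary_pixels(mask: np.ndarray, cls: int) -> set[tuple[int, int]]:
    """Inner-boundary pixels of ``cls`` under 4-connectivity."""
    m = mask == cls
    if not m.any():
        return set()
    # a class pixel is boundary if any 4-neighbour (with out-of-image padding
    # counting as outside) is not in the class
    padded = np.pad(m, 1, mode="constant", constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    boundary = m & ~interior
    return {(int(r), int(c)) for r, c in np.argwhere(boundary)}


def _boundary_mask(mask: np.ndarray, cls: int) -> np.ndarray:
    m = mask == cls
    padded = np.pad(m, 1, mode="constant", constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    return m & ~interior


def assd_hd(pred: np.ndarray, gt: np.ndarray, cls: int) -> tuple[float, float]:
    """Average symmetric surface distance and Hausdorff distance (pixels).

    Uses Euclidean distance transforms, which is exact for distances between
    pixel centers.
    """
    _check_shapes(pred, gt)
    a = _boundary_mask(pred, cls)
    b = _boundary_mask(gt, cls)
    if not a.any() and not b.any():
        return 0.0, 0.0
    if not a.any() or not b.any():
        sentinel = float(np.hypot(*pred.shape))
        return sentinel, sentinel
    dist_to_b = distance_transform_edt(~b)
    dist_to_a = distance_transform_edt(~a)
    d_ab = dist_to_b[a]
    d_ba = dist_to_a[b]
    assd = 0.5 * (d_ab.mean() + d_ba.mean())
    hd = max(d_ab.max(), d_ba.max())
    return float(assd), float(hd)


def evaluate_pair(pred: np.ndarray, gt: np.ndarray,
                  boundary_cls: int = 1) -> MetricsReport:
    """Full report for one prediction/ground-truth pair.

    Boundary metrics are reported for the dissection zone (class 1), whose
    delineation is the clinically relevant one.
    """
    iou_pc, dice_pc = {}, {}
    for cls in (0, 1):
        iou_pc[cls], dice_pc[cls] = iou_dice(pred, gt, cls)
    assd, hd = assd_hd(pred, gt, boundary_cls)
    return MetricsReport(
        iou_per_class=iou_pc,
        dice_per_class=dice_pc,
        mean_iou=mean_over_classes(iou_pc),
        mean_dice=mean_over_classes(dice_pc),
        assd=assd,
        hd=hd,
    )


def aggregate_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Dataset-level report: mean over images of per-image metrics."""
    if not reports:
        raise ValueError("no reports to aggregate")
    iou_pc = {c: float(np.mean([r.iou_per_class[c] for r in reports])) for c in (0, 1)}
    dice_pc = {c: float(np.mean([r.dice_per_class[c] for r in reports])) for c in (0, 1)}
    return MetricsReport(
        iou_per_class=iou_pc,
        dice_per_class=dice_pc,
        mean_iou=float(np.mean([r.mean_iou for r in reports])),
        mean_dice=float(np.mean([r.mean_dice for r in reports])),
        assd=float(np.mean([r.assd for r in reports])),
        hd=float(np.mean([r.hd for r in reports])),
    )
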