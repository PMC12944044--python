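"""Segmentation evaluation metrics: Dice, IoU and the 95th-percentile
Hausdorff distance, plus batch evaluation over a dataset.

Conventions (documented because the formulas leave degenerate cases open):

* Dice and IoU of two empty masks are 1; empty vs non-empty is 0.
* HD95 uses boundary pixels (foreground pixels with at least one background
  4-neighbour, image border counted as background), Euclidean distances,
  linear-interpolation percentiles, and symmetrizes as
  ``max(P95(d_pred→gt), P95(d_gt→pred))``.
* If either mask has no boundary, HD95 returns the image diagonal as a
  sentinel; such values are flagged and excluded from means.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage


def dice_coefficient(pred: np.ndarray, gt: np.ndarray) -> float:
    """Region overlap 2|X∩Y| / (|X|+|Y|) between two binary masks."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError("mask shapes differ")
    px, py = pred.sum(), gt.sum()
    if px + py == 0:
        return 1.0
    return 2.0 * np.logical_and(pred, gt).sum() / (px + py)


def iou(pred: np.ndarray, gt: np.ndarray) -> float:
    """Intersection over union TP / (TP + FP + FN)."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError("mask shapes differ")
    union = np.logical_or(pred, gt).sum()
    if union == 0:
        return 1.0
    return np.logical_and(pred, gt).sum() / union


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with >= 1 background 4-neighbour (border = background)."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return mask & ~interior


def hd95(pred: np.ndarray, gt: np.ndarray, spacing=(1.0, 1.0)):
    """95th-percentile symmetric Hausdorff distance between mask boundaries.

    Returns ``(value, valid)``; ``valid`` is False when either boundary is
    empty, in which case ``value`` is the image-diagonal sentinel.
    """
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError("mask shapes differ")
    bp = boundary_pixels(pred)
    bg = boundary_pixels(gt)
    h, w = pred.shape
    if not bp.any() or not bg.any():
        diagonal = float(np.hypot(h * spacing[0], w * spacing[1]))
        return diagonal, False
    # Euclidean distance to the nearest boundary pixel of the other mask
    dist_to_gt = ndimage.distance_transform_edt(~bg, sampling=spacing)
    dist_to_pred = ndimage.distance_transform_edt(~bp, sampling=spacing)
    d_pred_gt = dist_to_gt[bp]
    d_gt_pred = dist_to_pred[bg]
    value = max(
        float(np.percentile(d_pred_gt, 95, method="linear")),
        float(np.percentile(d_gt_pred, 95, method="linear")),
    )
    return value, True


@dataclasses.dataclass
class MetricsReport:
    """Per-class and mean Dice / IoU / HD95 over an evaluation set."""

    per_class_dice: np.ndarray
    per_class_iou: np.ndarray
    per_class_hd95: np.ndarray
    mean_dice: float
    mean_iou: float
    mean_hd95: float
    n_cases: int
    per_case: list  # list of dicts, one per case

    def to_dict(self) -> dict:
        return {
            "per_case": self.per_case,
            "per_class": {
                "dice": self.per_class_dice.tolist(),
                "iou": self.per_class_iou.tolist(),
                "hd95": self.per_class_hd95.tolist(),
            },
            "means": {
                "dice": self.mean_dice,
                "iou": self.mean_iou,
                "hd95": self.mean_hd95,
            },
            "n_cases": self.n_cases,
        }

    def save(self, json_path, csv_path=None) -> None:
        with open(json_path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
        if csv_path is not None:
            import pandas as pd

            pd.DataFrame(self.per_case).to_csv(csv_path, index=False)


def evaluate_cases(predict_fn, dataset, num_fg_classes: int) -> MetricsReport:
    """Evaluate a predictor over labelled cases.

    ``predict_fn`` maps an image (H,W) or (H,W,C) to an integer label map;
    ``dataset`` is an iterable of objects with ``image`` and ``label_map``.
    Metrics are computed per case and per foreground class, then averaged
    (HD95 sentinel cases are excluded from the means).
    """
    k = num_fg_classes
    rows = []
    for idx, sample in enumerate(dataset):
        pred = np.asarray(predict_fn(sample.image))
        gt = np.asarray(sample.label_map)
        row = {"case": idx}
        for c in range(1, k + 1):
            pm, gm = pred == c, gt == c
            h95, valid = hd95(pm, gm)
            row[f"dice_{c}"] = dice_coefficient(pm, gm)
            row[f"iou_{c}"] = iou(pm, gm)
            row[f"hd95_{c}"] = h95
            row[f"hd95_{c}_valid"] = bool(valid)
        rows.append(row)
    if not rows:
        raise ValueError("dataset is empty")

    per_class_dice = np.array([np.mean([r[f"dice_{c}"] for r in rows])
                               for c in range(1, k + 1)])
    per_class_iou = np.array([np.mean([r[f"iou_{c}"] for r in rows])
                              for c in range(1, k + 1)])
    per_class_hd = []
    for c in range(1, k + 1):
        vals = [r[f"hd95_{c}"] for r in rows if r[f"hd95_{c}_valid"]]
        per_class_hd.append(np.mean(vals) if vals else np.nan)
    per_class_hd = np.array(per_class_hd)

    finite_hd = per_class_hd[np.isfinite(per_class_hd)]
    return MetricsReport(
        per_class_dice=per_class_dice,
        per_class_iou=per_class_iou,
        per_class_hd95=per_class_hd,
        mean_dice=float(per_class_dice.mean()),
        mean_iou=float(per_class_iou.mean()),
        mean_hd95=float(finite_hd.mean()) if finite_hd.size else float("nan"),
        n_cases=len(rows),
        per_case=rows,
    )
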