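"""Segmentation evaluation metrics: Dice, IoU and the 95th-percentile
Hausdorff distance, with mean +/- SD study aggregation."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["dice_coefficient", "iou", "hd95", "evaluate", "MetricReport"]


def _binarize(a) -> np.ndarray:
    return np.asarray(a) > 0


def dice_coefficient(a, b) -> float:
    """DSC = 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    a, b = _binarize(a), _binarize(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def iou(a, b) -> float:
    """IoU = |A n B| / |A u B|; 1.0 when both masks are empty."""
    a, b = _binarize(a), _binarize(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    return int((a & b).sum()) / union


def _surface(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: mask minus its erosion."""
    eroded = ndimage.binary_erosion(mask, border_value=0)
    return mask & ~eroded


def _diagonal_mm(shape, spacing) -> float:
    return math.sqrt(sum((s * sp) ** 2 for s, sp in zip(shape, spacing)))


def hd95(a, b, spacing=None) -> float:
    """95th percentile of the symmetric surface distances, in mm.

    Identical masks give 0.  If exactly one mask is empty the distance is
    undefined; the image diagonal is returned so aggregates stay finite
    (`evaluate` flags such studies).  Both empty gives 0.
    """
    a, b = _binarize(a), _binarize(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    spacing = tuple(spacing) if spacing is not None else (1.0,) * a.ndim
    ea, eb = a.any(), b.any()
    if not ea and not eb:
        return 0.0
    if ea != eb:
        return _diagonal_mm(a.shape, spacing)
    sa, sb = _surface(a), _surface(b)
    # distance maps to the other mask's surface, sampled on this surface
    da = ndimage.distance_transform_edt(~sb, sampling=spacing)[sa]
    db = ndimage.distance_transform_edt(~sa, sampling=spacing)[sb]
    return float(np.percentile(np.concatenate([da, db]), 95))


@dataclass
class MetricReport:
    """Per-study metrics plus mean +/- population-SD aggregates."""

    per_study: pd.DataFrame
    summary: dict

    def to_csv(self, path) -> None:
        self.per_study.to_csv(path, index=False)


def evaluate(pred_masks, true_masks, spacing=None, study_ids=None) -> MetricReport:
    """Compute DSC / IoU / HD95 for matched mask lists and aggregate."""
    if len(pred_masks) != len(true_masks):
        raise ValueError("prediction and reference lists differ in length")
    ids = study_ids if study_ids is not None else list(range(len(pred_masks)))
    rows = []
    for sid, p, t in zip(ids, pred_masks, true_masks):
        p, t = _binarize(p), _binarize(t)
        defined = p.any() == t.any()
        rows.append({"study": sid,
                     "dsc": dice_coefficient(p, t),
                     "iou": iou(p, t),
                     "hd95": hd95(p, t, spacing),
                     "hd95_defined": bool(defined)})
    df = pd.DataFrame(rows)
    summary = {}
    for m in ("dsc", "iou", "hd95"):
        summary[f"{m}_mean"] = float(df[m].mean())
        summary[f"{m}_sd"] = float(df[m].std(ddof=0))  # population SD
    return MetricReport(per_study=df, summary=summary)
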