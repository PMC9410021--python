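"""Evaluation metrics for vertebra detection and identification.

* per-pixel classification rate over true spine pixels (background ignored)
* centroid identification rate: a vertebra counts as identified when the
  predicted centroid of the *same id* lies within 20 mm of the truth
  (matching is by id, never nearest-neighbour — swapped labels are errors)
* mean / population-std centroid distance over ids present in both sets
* binary segmentation metrics (accuracy, recall, IoU, dice), micro-averaged
  over both classes ("overall") and for the vertebra class alone
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import BinaryMask, CentroidSet
from .labels import DenseLabels

ID_THRESHOLD_MM = 20.0

REGIONS = ("cervical", "thoracic", "lumbar", "sacral")


def region_of(vertebra_id: int) -> str:
    """Spine region of a vertebra id: C1-C7, T1-T12, L1-L5, S1-S2."""
    vid = int(vertebra_id)
    if not 1 <= vid <= 26:
        raise ValueError(f"vertebra id {vid} outside 1..26")
    if vid <= 7:
        return "cervical"
    if vid <= 19:
        return "thoracic"
    if vid <= 24:
        return "lumbar"
    return "sacral"


@dataclass
class SegScores:
    accuracy: float
    recall: float
    iou: float
    dice: float

    def as_dict(self):
        return vars(self).copy()


@dataclass
class EvalReport:
    pixel_rate: float | None = None
    id_rate: float | None = None
    mean_dist_mm: float | None = None
    std_dist_mm: float | None = None
    seg_overall: SegScores | None = None
    seg_vertebrae: SegScores | None = None
    region_breakdown: dict[str, float | None] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "pixel_rate": self.pixel_rate,
            "id_rate": self.id_rate,
            "mean_dist_mm": self.mean_dist_mm,
            "std_dist_mm": self.std_dist_mm,
            "region_breakdown": dict(self.region_breakdown),
        }
        out["seg_overall"] = self.seg_overall.as_dict() if self.seg_overall else None
        out["seg_vertebrae"] = (
            self.seg_vertebrae.as_dict() if self.seg_vertebrae else None
        )
        return out


def pixel_classification_rate(pred: DenseLabels, truth: DenseLabels) -> float:
    """Fraction of true spine pixels carrying the correct vertebra label."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    spine = truth.data > 0
    n = int(spine.sum())
    if n == 0:
        raise ValueError("truth contains no spine pixels; the rate is undefined")
    return float(np.sum(pred.data[spine] == truth.data[spine]) / n)


def id_rate(
    pred: CentroidSet,
    truth: CentroidSet,
    threshold_mm: float = ID_THRESHOLD_MM,
) -> tuple[float, dict[int, bool]]:
    """Identification rate plus the per-vertebra correctness flags.

    A truth vertebra is identified iff the prediction contains the same id
    within ``threshold_mm`` (inclusive); missing ids count as incorrect.
    """
    if len(truth) == 0:
        raise ValueError("truth centroid set is empty; the rate is undefined")
    flags: dict[int, bool] = {}
    for vid, pos in truth.items():
        ok = False
        if vid in pred:
            ok = float(np.linalg.norm(pred[vid] - pos)) <= threshold_mm
        flags[vid] = ok
    return sum(flags.values()) / len(flags), flags


def distance_stats(pred: CentroidSet, truth: CentroidSet) -> tuple[float, float]:
    """Mean and population standard deviation (mm) of centroid distances over
    ids present in both sets."""
    common = [vid for vid in truth.ids() if vid in pred]
    if not common:
        raise ValueError("no vertebra id present in both centroid sets")
    d = np.array([np.linalg.norm(pred[v] - truth[v]) for v in common])
    return float(d.mean()), float(d.std())


def _scores(tp, fp, fn, tn) -> SegScores:
    total = tp + fp + fn + tn
    acc = (tp + tn) / total if total else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    iou = tp / (tp + fp + fn) if tp + fp + fn else float("nan")
    dice = 2 * tp / (2 * tp + fp + fn) if tp + fp + fn else float("nan")
    return SegScores(float(acc), float(recall), float(iou), float(dice))


def segmentation_metrics(pred: BinaryMask, truth: BinaryMask) -> dict[str, SegScores]:
    """Overall (micro over both classes) and vertebrae-only scores."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.data.astype(bool)
    t = truth.data.astype(bool)
    if not t.any():
        raise ValueError("truth spine is empty; vertebrae-only metrics undefined")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    vertebrae = _scores(tp, fp, fn, tn)
    # micro-average over both classes: every voxel is one prediction of its class
    overall = _scores(tp + tn, fn + fp, fp + fn, 0)
    overall = SegScores(
        accuracy=(tp + tn) / (tp + tn + fp + fn),
        recall=overall.recall,
        iou=overall.iou,
        dice=overall.dice,
    )
    return {"overall": overall, "vertebrae": vertebrae}


def evaluate_identification(
    pred_dense: DenseLabels,
    pred_centroids: CentroidSet,
    truth_dense: DenseLabels,
    truth_centroids: CentroidSet,
    threshold_mm: float = ID_THRESHOLD_MM,
) -> EvalReport:
    """Bundle all identification metrics for one scan."""
    rate, flags = id_rate(pred_centroids, truth_centroids, threshold_mm)
    try:
        mean_d, std_d = distance_stats(pred_centroids, truth_centroids)
    except ValueError:
        mean_d = std_d = None
    per_region: dict[str, float | None] = {}
    for region in REGIONS:
        ids = [v for v in flags if region_of(v) == region]
        per_region[region] = (
            sum(flags[v] for v in ids) / len(ids) if ids else None
        )
    return EvalReport(
        pixel_rate=pixel_classification_rate(pred_dense, truth_dense),
        id_rate=rate,
        mean_dist_mm=mean_d,
        std_dist_mm=std_d,
        region_breakdown=per_region,
    )
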