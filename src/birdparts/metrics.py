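"""Detection and classification evaluation: precision, recall, AP, mAP.

Detections are matched to ground truth per class: sorted by descending
confidence, each detection greedily claims the unclaimed ground-truth box of
highest IoU at or above the threshold (true positive), otherwise it is a
false positive; unclaimed ground truths are false negatives.

Average precision uses all-point interpolation over the cumulative
precision/recall curve: ``P_inter(r) = max precision at recall ≥ r`` and
``AP = Σ (r_{i+1} − r_i) · P_inter(r_{i+1})``.  mAP is the arithmetic mean of
the per-class APs over the classes that have ground truth; classes with
detections but no ground truth are excluded and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


def box_iou(box_a, box_b) -> float:
    """IoU of two 0-based half-open (xmin, ymin, xmax, ymax) boxes."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union


@dataclass
class DetectionMatch:
    """TP/FP flags per confidence-ranked detection, per class."""

    # class_id -> (confidences desc-sorted array, tp flags array)
    per_class: dict = field(default_factory=dict)
    # class_id -> number of ground-truth boxes
    gt_counts: dict = field(default_factory=dict)

    def totals(self):
        tp = sum(int(flags.sum()) for _, flags in self.per_class.values())
        n_det = sum(len(flags) for _, flags in self.per_class.values())
        n_gt = sum(self.gt_counts.values())
        return tp, n_det - tp, n_gt - tp  # TP, FP, FN


def _det_sort_key(det):
    # stable, order-free tie rule: confidence desc, then class, then box
    return (-det.confidence, det.class_id, tuple(det.box))


def match_detections(detections: list, ground_truth: list,
                     iou_threshold: float = 0.5) -> DetectionMatch:
    """Greedy per-class matching of detections against annotated boxes.

    `detections` are DetectionRecord-like (image_id, class_id, confidence,
    box); `ground_truth` are PartAnnotation-like (image_id, class_id, box).
    """
    match = DetectionMatch()
    gt_by_class: dict = {}
    for gt in ground_truth:
        gt_by_class.setdefault(gt.class_id, []).append(gt)
    for class_id, gts in gt_by_class.items():
        match.gt_counts[class_id] = len(gts)
    det_by_class: dict = {}
    for det in detections:
        det_by_class.setdefault(det.class_id, []).append(det)
    for class_id, dets in det_by_class.items():
        dets = sorted(dets, key=_det_sort_key)
        gts = gt_by_class.get(class_id, [])
        claimed = [False] * len(gts)
        conf = np.array([d.confidence for d in dets])
        tp = np.zeros(len(dets), dtype=bool)
        for i, det in enumerate(dets):
            best_iou, best_j = iou_threshold, -1
            for j, gt in enumerate(gts):
                if claimed[j] or gt.image_id != det.image_id:
                    continue
                iou = box_iou(det.box, gt.box)
                if iou >= best_iou and (best_j < 0 or iou > best_iou):
                    best_iou, best_j = iou, j
            if best_j >= 0:
                claimed[best_j] = True
                tp[i] = True
        match.per_class[class_id] = (conf, tp)
        match.gt_counts.setdefault(class_id, 0)
    return match


def precision_recall(match: DetectionMatch) -> tuple[float, float]:
    """Aggregate precision and recall over all classes (0 when undefined)."""
    tp, fp, fn = match.totals()
    if tp + fp == 0:
        logger.warning("precision undefined (no detections); reporting 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.warning("recall undefined (no ground truth); reporting 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    return precision, recall


def average_precision(match: DetectionMatch, class_id: int) -> float:
    """All-point interpolated AP for one class."""
    n_gt = match.gt_counts.get(class_id, 0)
    if n_gt == 0:
        raise ValueError(f"class {class_id} has no ground truth")
    conf, tp = match.per_class.get(class_id, (np.empty(0), np.empty(0, dtype=bool)))
    if len(conf) == 0 or not tp.any():
        return 0.0
    order = np.argsort(-conf, kind="stable")
    tp = tp[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    # prepend the r=0 point; P_inter = running max of precision from the right
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[1.0], precision])
    p_inter = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum((r[1:] - r[:-1]) * p_inter[1:]))


def mean_ap(ap_per_class: dict) -> float:
    """Arithmetic mean of per-class APs."""
    if not ap_per_class:
        raise ValueError("no classes with ground truth to average over")
    return float(np.mean(list(ap_per_class.values())))


@dataclass
class MetricsReport:
    precision: float
    recall: float
    ap_per_class: dict
    map50: float
    accuracy: float | None = None

    def to_dict(self):
        return {"precision": self.precision, "recall": self.recall,
                "map50": self.map50, "accuracy": self.accuracy,
                "ap_per_class": {int(k): v for k, v in self.ap_per_class.items()}}


def evaluate_detections(detections: list, ground_truth: list,
                        iou_threshold: float = 0.5,
                        accuracy_value: float | None = None) -> MetricsReport:
    """Full evaluation chain: match → precision/recall → per-class AP → mAP."""
    match = match_detections(detections, ground_truth, iou_threshold)
    precision, recall = precision_recall(match)
    evaluated = [c for c, n in match.gt_counts.items() if n > 0]
    skipped = [c for c in match.per_class if match.gt_counts.get(c, 0) == 0]
    if skipped:
        logger.info("excluding %d classes without ground truth from mAP",
                    len(skipped))
    ap = {c: average_precision(match, c) for c in evaluated}
    return MetricsReport(precision=precision, recall=recall, ap_per_class=ap,
                         map50=mean_ap(ap) if ap else 0.0,
                         accuracy=accuracy_value)
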