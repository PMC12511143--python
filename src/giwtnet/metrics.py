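"""Detection evaluation: IoU, greedy matching, precision/recall/F1, average
precision and the mAP@50 / mAP@50~95 suite.

Conventions
-----------
Boxes are (x1, y1, x2, y2) in pixels, 0-based, with x2 > x1 and y2 > y1.
Matching is class-wise and greedy: detections are processed in descending
confidence, each claiming the highest-IoU unmatched ground truth of its class
with IoU >= threshold; one match per ground truth.  AP uses 101-point
interpolation (precision envelope sampled at recall 0, 0.01, ..., 1.00); the
exact all-point envelope integral is available behind ``interpolation=
"exact"``.  Values are fractions internally; formatting to percent with one
decimal happens only at the reporting boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DetectionBox",
    "GroundTruthBox",
    "EvalResult",
    "iou",
    "box_iou_matrix",
    "match_detections",
    "precision_recall_f1",
    "average_precision",
    "map_suite",
    "nms",
    "IOU_THRESHOLDS_50_95",
]

logger = logging.getLogger(__name__)

IOU_THRESHOLDS_50_95 = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class GroundTruthBox:
    class_id: int
    box: tuple[float, float, float, float]

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not all(np.isfinite(self.box)):
            raise ValueError(f"box coordinates must be finite, got {self.box}")
        if x2 <= x1 or y2 <= y1:
            raise ValueError(f"box must have positive area, got {self.box}")


@dataclass(frozen=True)
class DetectionBox:
    class_id: int
    box: tuple[float, float, float, float]
    confidence: float = 1.0

    def __post_init__(self):
        if not all(np.isfinite(self.box)):
            raise ValueError(f"box coordinates must be finite, got {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass
class EvalResult:
    map50: float
    map50_95: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    per_class_ap: dict = field(default_factory=dict)  # class_id -> {thr: AP}
    conf_threshold: float = 0.25

    def as_percent_row(self) -> str:
        return (
            f"P {100 * self.precision:.1f}%  R {100 * self.recall:.1f}%  "
            f"F1 {100 * self.f1:.1f}%  mAP@50 {100 * self.map50:.1f}%  "
            f"mAP@50~95 {100 * self.map50_95:.1f}%"
        )


def iou(a, b) -> float:
    """Intersection over union of two xyxy boxes; 0 for disjoint or degenerate."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    area_a = max(0.0, ax2 - ax1) * max(0.0, ay2 - ay1)
    area_b = max(0.0, bx2 - bx1) * max(0.0, by2 - by1)
    if area_a == 0.0 or area_b == 0.0:
        logger.warning("degenerate zero-area box in IoU: %s vs %s", a, b)
        return 0.0
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (N,4) vs (M,4) xyxy arrays."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    iw = np.clip(np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0]), 0, None)
    ih = np.clip(np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1]), 0, None)
    inter = iw * ih
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def match_detections(dets: list[DetectionBox], gts: list[GroundTruthBox],
                     iou_thr: float = 0.5):
    """Greedy class-wise matching within one image.

    Returns (tp_flags aligned with dets sorted by descending confidence,
    the sorted detections, fn_count).
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    sorted_dets = [dets[i] for i in order]
    matched = [False] * len(gts)
    tp_flags = np.zeros(len(dets), dtype=bool)
    for di, det in enumerate(sorted_dets):
        best, best_iou = -1, iou_thr
        for gi, gt in enumerate(gts):
            if matched[gi] or gt.class_id != det.class_id:
                continue
            v = iou(det.box, gt.box)
            if v >= best_iou:
                best, best_iou = gi, v
        if best >= 0:
            matched[best] = True
            tp_flags[di] = True
    fn = matched.count(False)
    return tp_flags, sorted_dets, fn


def precision_recall_f1(tp: float, fp: float, fn: float):
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = harmonic mean; 0/0 -> 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def average_precision(tp_flags, gt_count: int, interpolation: str = "101") -> float:
    """AP from confidence-ordered TP/FP flags of one class.

    ``interpolation='101'`` samples the precision envelope at recalls
    0, 0.01, ..., 1.00; ``'exact'`` integrates the envelope over all points.
    Classes without ground truth are the caller's responsibility to exclude.
    """
    tp_flags = np.asarray(tp_flags, dtype=bool)
    if gt_count <= 0:
        raise ValueError("gt_count must be positive; exclude empty classes upstream")
    if tp_flags.size == 0:
        return 0.0
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / gt_count
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope (non-increasing from the right)
    env_r = np.concatenate([[0.0], recall, [1.0]])
    env_p = np.concatenate([[0.0], precision, [0.0]])
    for i in range(env_p.size - 2, -1, -1):
        env_p[i] = max(env_p[i], env_p[i + 1])
    if interpolation == "101":
        samples = np.linspace(0.0, 1.0, 101)
        idx = np.searchsorted(env_r, samples, side="left")
        return float(env_p[idx].mean())
    if interpolation == "exact":
        i = np.where(env_r[1:] != env_r[:-1])[0]
        return float(np.sum((env_r[i + 1] - env_r[i]) * env_p[i + 1]))
    raise ValueError(f"unknown interpolation {interpolation!r}")


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float = 0.45) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices (desc. score)."""
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 4)
    scores = np.asarray(scores, dtype=np.float64)
    order = np.argsort(-scores)
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        rest = order[~suppressed[order]]
        rest = rest[rest != i]
        if rest.size:
            ious = box_iou_matrix(boxes[i][None], boxes[rest])[0]
            suppressed[rest[ious > iou_thr]] = True
    return np.asarray(keep, dtype=int)


def map_suite(dets_by_image: dict[object, list[DetectionBox]],
              gts_by_image: dict[object, list[GroundTruthBox]],
              iou_thresholds=IOU_THRESHOLDS_50_95,
              conf_threshold: float = 0.25,
              interpolation: str = "101") -> EvalResult:
    """Full evaluation over a set of images.

    mAP@50 is the class-mean AP at IoU 0.5; mAP@50~95 averages the class-mean
    AP over thresholds 0.50..0.95 (step 0.05).  P/R/F1 are computed at
    ``conf_threshold`` and IoU 0.5.  Classes with no ground truth anywhere are
    excluded from the class means (and logged).
    """
    image_ids = sorted(set(dets_by_image) | set(gts_by_image), key=str)
    classes = sorted({g.class_id for gs in gts_by_image.values() for g in gs})
    gt_count = {c: 0 for c in classes}
    for gs in gts_by_image.values():
        for g in gs:
            gt_count[g.class_id] += 1
    present_dets = {d.class_id for ds in dets_by_image.values() for d in ds}
    for c in present_dets - set(classes):
        logger.info("class %s has detections but no ground truth; excluded from mAP", c)

    # accumulate confidence-ordered flags per class per threshold
    per_class_ap: dict[int, dict[float, float]] = {c: {} for c in classes}
    records: dict[float, dict[int, list[tuple[float, bool]]]] = {
        thr: {c: [] for c in classes} for thr in iou_thresholds
    }
    for img in image_ids:
        dets = dets_by_image.get(img, [])
        gts = gts_by_image.get(img, [])
        for thr in iou_thresholds:
            tp_flags, sorted_dets, _ = match_detections(dets, gts, thr)
            for flag, det in zip(tp_flags, sorted_dets):
                if det.class_id in records[thr]:
                    records[thr][det.class_id].append((det.confidence, bool(flag)))

    ap_means = {}
    for thr in iou_thresholds:
        aps = []
        for c in classes:
            if gt_count[c] == 0:
                logger.info("class %s has no ground truth; excluded", c)
                continue
            recs = sorted(records[thr][c], key=lambda t: -t[0])
            ap = average_precision([f for _, f in recs], gt_count[c], interpolation)
            per_class_ap[c][float(thr)] = ap
            aps.append(ap)
        ap_means[thr] = float(np.mean(aps)) if aps else 0.0

    map50 = ap_means.get(0.5, 0.0)
    map50_95 = float(np.mean([ap_means[t] for t in iou_thresholds])) if ap_means else 0.0

    # operating-point counts at conf_threshold, IoU 0.5
    tp = fp = fn = 0
    for img in image_ids:
        dets = [d for d in dets_by_image.get(img, []) if d.confidence >= conf_threshold]
        gts = gts_by_image.get(img, [])
        tp_flags, _, fn_i = match_detections(dets, gts, 0.5)
        tp += int(tp_flags.sum())
        fp += int((~tp_flags).sum())
        fn += fn_i
    p, r, f1 = precision_recall_f1(tp, fp, fn)
    return EvalResult(map50, map50_95, p, r, f1, tp, fp, fn,
                      per_class_ap, conf_threshold)
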