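"""Detection evaluation: IoU matching, PR curves, AP/mAP@0.5, NMS, speed.

Definitions follow the standard single-threshold protocol:

* a prediction matches the highest-IoU unmatched same-class ground truth with
  IoU >= threshold (greedy in descending confidence) -> TP, else FP;
  unmatched ground truths are FN;
* precision = TP/(TP+FP), recall = TP/(TP+FN);
* AP is the area under the precision-recall curve, integrated with all-point
  interpolation over the monotone (right-to-left maximum) precision envelope;
* mAP is the unweighted mean of per-class APs over classes that have ground
  truth; classes without ground truth have undefined AP and are excluded.

Detection has no true negatives; the TN slot exists only for confusion-matrix
completeness and never enters any metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Detection:
    class_id: int
    confidence: float
    box: tuple[float, float, float, float]  # pixel-space x1, y1, x2, y2

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence outside [0,1]: {self.confidence}")
        x1, y1, x2, y2 = self.box
        if x2 <= x1 or y2 <= y1:
            raise ValueError(f"degenerate box {self.box}")


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0  # carried for table fidelity; unused in detection metrics


@dataclass
class PRCurve:
    """Cumulative precision/recall points swept over descending confidence."""

    confidences: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    n_gt: int


def iou(a, b) -> float:
    """Intersection-over-union of two xyxy boxes."""
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix2 - ix1), max(0.0, iy2 - iy1)
    inter = iw * ih
    union = ((a[2] - a[0]) * (a[3] - a[1])
             + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return inter / union if union > 0 else 0.0


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (N,4) x (M,4) xyxy arrays."""
    if len(boxes_a) == 0 or len(boxes_b) == 0:
        return np.zeros((len(boxes_a), len(boxes_b)))
    a, b = np.asarray(boxes_a, float), np.asarray(boxes_b, float)
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def nms(dets: list[Detection], iou_thr: float = 0.7,
        conf_thr: float = 0.001) -> list[Detection]:
    """Greedy per-class non-maximum suppression; output sorted by confidence."""
    dets = [d for d in dets if d.confidence >= conf_thr]
    dets.sort(key=lambda d: -d.confidence)
    keep: list[Detection] = []
    for d in dets:
        if all(k.class_id != d.class_id or iou(k.box, d.box) <= iou_thr
               for k in keep):
            keep.append(d)
    return keep


def match_detections(dets: list[Detection], gts, iou_thr: float = 0.5
                     ) -> tuple[ConfusionCounts, list[bool]]:
    """Greedy one-to-one matching of predictions to ground truth.

    ``gts`` is a list of (class_id, xyxy-box) pairs (or objects with
    ``class_id``/``box`` attributes).  Returns confusion counts and a
    per-detection TP flag list in descending-confidence order.
    """
    gts = [(g.class_id, g.box) if hasattr(g, "class_id") else tuple(g)
           for g in gts]
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    matched = [False] * len(gts)
    flags = [False] * len(dets)
    for i in order:
        d = dets[i]
        best_j, best_iou = -1, iou_thr
        for j, (gcid, gbox) in enumerate(gts):
            if matched[j] or gcid != d.class_id:
                continue
            v = iou(d.box, gbox)
            if v >= best_iou:
                best_iou, best_j = v, j
        if best_j >= 0:
            matched[best_j] = True
            flags[i] = True
    tp = sum(flags)
    counts = ConfusionCounts(TP=tp, FP=len(dets) - tp,
                             FN=len(gts) - tp)
    return counts, [flags[i] for i in order]


def precision(c: ConfusionCounts) -> float:
    return c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else 0.0


def recall(c: ConfusionCounts) -> float:
    return c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else 0.0


def pr_curve(confidences, tp_flags, n_gt: int) -> PRCurve:
    """Cumulative PR points from per-detection TP flags (any input order)."""
    conf = np.asarray(confidences, float)
    tp = np.asarray(tp_flags, bool)
    order = np.argsort(-conf)
    conf, tp = conf[order], tp[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(~tp)
    prec = cum_tp / np.maximum(cum_tp + cum_fp, 1)
    rec = cum_tp / n_gt if n_gt > 0 else np.zeros_like(cum_tp, dtype=float)
    return PRCurve(conf, prec, rec, n_gt)


def average_precision(curve: PRCurve) -> float:
    """Area under the PR curve, all-point interpolation, monotone envelope."""
    if curve.n_gt == 0:
        raise ValueError("AP undefined for a class with no ground truth")
    if len(curve.recall) == 0:
        return 0.0
    rec = np.concatenate(([0.0], curve.recall, [curve.recall[-1]]))
    prec = np.concatenate(([1.0], curve.precision, [0.0]))
    # monotone non-increasing envelope from the right
    prec = np.maximum.accumulate(prec[::-1])[::-1]
    idx = np.where(rec[1:] != rec[:-1])[0]
    return float(np.sum((rec[idx + 1] - rec[idx]) * prec[idx + 1]))


def map50(per_class_ap: list[float]) -> float:
    """Unweighted mean of per-class APs."""
    if len(per_class_ap) == 0:
        raise ValueError("mAP undefined with zero classes")
    return float(np.mean(per_class_ap))


@dataclass
class EvalResult:
    per_class_ap: dict[int, float]
    map50: float
    counts: ConfusionCounts
    skipped_classes: list[int] = field(default_factory=list)


def evaluate_detections(per_image: list[tuple[list[Detection], list]],
                        num_classes: int, iou_thr: float = 0.5) -> EvalResult:
    """Dataset-level mAP@`iou_thr` from (detections, ground truths) per image.

    Ground truths are (class_id, xyxy) pairs.  Classes with no ground truth
    anywhere are flagged and excluded from the mean.
    """
    confs: dict[int, list] = {c: [] for c in range(num_classes)}
    flags: dict[int, list] = {c: [] for c in range(num_classes)}
    n_gt = {c: 0 for c in range(num_classes)}
    total = ConfusionCounts()
    for dets, gts in per_image:
        gts = [(g.class_id, g.box) if hasattr(g, "class_id") else tuple(g)
               for g in gts]
        for c in range(num_classes):
            dc = [d for d in dets if d.class_id == c]
            gc = [g for g in gts if g[0] == c]
            counts, fl = match_detections(dc, gc, iou_thr)
            order = sorted(dc, key=lambda d: -d.confidence)
            confs[c].extend(d.confidence for d in order)
            flags[c].extend(fl)
            n_gt[c] += len(gc)
            total.TP += counts.TP
            total.FP += counts.FP
            total.FN += counts.FN
    aps: dict[int, float] = {}
    skipped = []
    for c in range(num_classes):
        if n_gt[c] == 0:
            skipped.append(c)
            continue
        aps[c] = average_precision(pr_curve(confs[c], flags[c], n_gt[c]))
    if not aps:
        raise ValueError("no class has ground truth; mAP undefined")
    return EvalResult(aps, map50(list(aps.values())), total, skipped)


def measure_speed(times: list[float]) -> float:
    """Mean per-image processing time (seconds)."""
    if len(times) == 0:
        raise ValueError("cannot average an empty timing list")
    return float(np.mean(times))
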