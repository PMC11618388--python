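"""Precision, recall and AP@0.5 for single-class detection.

Definitions: P = TP/(TP+FP), R = TP/(TP+FN); a detection is a true
positive when its IoU with an unmatched ground-truth box exceeds the
threshold (0.5 by default), matched greedily in descending confidence with
each ground truth used at most once.  AP is the area under the P(R) curve,
integrated exactly over the monotone-decreasing precision envelope (the
"all points" scheme).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["iou", "match", "average_precision", "evaluate", "EvalResult"]


def iou(a, b) -> float:
    """Intersection-over-union of two (x1, y1, x2, y2) boxes.

    Degenerate (zero-area) boxes overlap nothing by definition."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    area_a = max(ax2 - ax1, 0.0) * max(ay2 - ay1, 0.0)
    area_b = max(bx2 - bx1, 0.0) * max(by2 - by1, 0.0)
    if area_a == 0.0 or area_b == 0.0:
        return 0.0
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def match(det_boxes, det_conf, gt_boxes, iou_thr: float = 0.5):
    """Greedy one-to-one detection/ground-truth matching.

    Detections are visited in descending confidence; each claims the
    highest-IoU unmatched ground truth above the threshold.  Returns
    (tp_flags aligned with the confidence-sorted order, sort order, fn).
    """
    det_boxes = np.asarray(det_boxes, dtype=float).reshape(-1, 4)
    det_conf = np.asarray(det_conf, dtype=float).reshape(-1)
    gt_boxes = np.asarray(gt_boxes, dtype=float).reshape(-1, 4)
    order = np.argsort(-det_conf, kind="stable")
    taken = np.zeros(len(gt_boxes), dtype=bool)
    tp = np.zeros(len(det_boxes), dtype=bool)
    for rank, di in enumerate(order):
        best, best_iou = -1, iou_thr
        for gi in range(len(gt_boxes)):
            if taken[gi]:
                continue
            v = iou(det_boxes[di], gt_boxes[gi])
            if v > best_iou:
                best, best_iou = gi, v
        if best >= 0:
            taken[best] = True
            tp[rank] = True
    fn = int((~taken).sum())
    return tp, order, fn


def average_precision(tp_flags: Sequence[bool], confidences: Sequence[float],
                      n_gt: int):
    """AP from per-detection TP/FP labels and confidences.

    Builds the cumulative precision/recall curve over descending
    confidence and integrates the exact step curve of the monotone
    precision envelope.  Returns (ap, recall_curve, precision_curve).
    """
    if n_gt < 1:
        raise ValueError("average precision undefined with zero ground truths")
    tp_flags = np.asarray(tp_flags, dtype=bool)
    confidences = np.asarray(confidences, dtype=float)
    order = np.argsort(-confidences, kind="stable")
    tp = tp_flags[order].astype(float)
    ctp = np.cumsum(tp)
    cfp = np.cumsum(1.0 - tp)
    recall = ctp / n_gt
    precision = ctp / np.maximum(ctp + cfp, 1e-12)
    # monotone envelope + exact step integration
    mrec = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    ap = float(np.sum((mrec[1:] - mrec[:-1]) * mpre[1:]))
    return ap, recall, precision


@dataclass
class EvalResult:
    """Dataset-level evaluation summary at a fixed IoU threshold."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    ap: float
    pr_points: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def to_dict(self):
        return {"TP": self.tp, "FP": self.fp, "FN": self.fn,
                "P": self.precision, "R": self.recall, "AP50": self.ap}


def evaluate(model, dataset, conf_thr: float = 0.001, iou_thr: float = 0.5,
             predictions=None) -> EvalResult:
    """Evaluate a detector (or precomputed predictions) on a labelled set.

    ``dataset`` is a sequence of objects with ``image`` (HxWx3 uint8) and
    ``labels`` (K x 5 normalised class/cx/cy/w/h rows).  AP is computed
    over all confidences; the headline P and R are reported at the
    confidence maximising F1 along the curve.
    """
    from .model import predict as _predict

    if predictions is None:
        predictions = _predict(model, [item.image for item in dataset],
                               conf_thr=conf_thr, iou_thr=0.45)
    all_tp, all_conf, n_gt = [], [], 0
    for item, det in zip(dataset, predictions):
        h, w = item.image.shape[:2]
        gl = np.asarray(item.labels, dtype=float).reshape(-1, 5)
        gt = np.empty((len(gl), 4))
        gt[:, 0] = (gl[:, 1] - gl[:, 3] / 2) * w
        gt[:, 1] = (gl[:, 2] - gl[:, 4] / 2) * h
        gt[:, 2] = (gl[:, 1] + gl[:, 3] / 2) * w
        gt[:, 3] = (gl[:, 2] + gl[:, 4] / 2) * h
        n_gt += len(gt)
        tp, order, _ = match(det.boxes, det.confidences, gt, iou_thr)
        all_tp.append(tp)
        all_conf.append(np.asarray(det.confidences, dtype=float)[order])
    tp_cat = np.concatenate(all_tp) if all_tp else np.zeros(0, dtype=bool)
    conf_cat = np.concatenate(all_conf) if all_conf else np.zeros(0)
    if n_gt == 0:
        raise ValueError("dataset has no ground-truth boxes")
    if len(tp_cat) == 0:
        return EvalResult(0, 0, n_gt, 0.0, 0.0, 0.0)
    ap, rec, pre = average_precision(tp_cat, conf_cat, n_gt)
    f1 = 2 * pre * rec / np.maximum(pre + rec, 1e-12)
    i = int(np.argmax(f1))
    tp_n = int(round(rec[i] * n_gt))
    order = np.argsort(-conf_cat, kind="stable")
    n_det = i + 1
    fp_n = n_det - int(tp_cat[order][:n_det].sum())
    return EvalResult(tp_n, fp_n, n_gt - tp_n, float(pre[i]), float(rec[i]),
                      ap, np.stack([rec, pre], axis=1))
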