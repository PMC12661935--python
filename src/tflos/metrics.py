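"""Detection and counting evaluation.

Implements the confusion-matrix family (precision, recall, F1), IoU-based
greedy matching of detections to ground truths, per-class average precision
by exact integration of the precision-recall step function, mAP at a single
IoU threshold and averaged over the 0.50:0.05:0.95 range, the coefficient
of determination R² for predicted-versus-actual counts, and multi-class
accuracy.

Matching rule (the metric definitions leave it open; fixed here): per image
and class, detections are taken in decreasing confidence — ties broken by
higher best-IoU, then input order — and each is matched one-to-one to the
unmatched ground truth of highest IoU.  A detection is a true positive iff
that IoU reaches the threshold; unmatched detections are false positives
and unmatched truths false negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .boxes import box_iou

log = logging.getLogger(__name__)

MAP_RANGE_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass
class ConfusionCounts:
    """TP/FP/FN/TN tallies; addition merges disjoint evaluation batches."""
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other):
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def precision(c: ConfusionCounts) -> float:
    denom = c.tp + c.fp
    if denom == 0:
        log.debug("precision undefined (no detections); returning 0")
        return 0.0
    return c.tp / denom


def recall(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn
    if denom == 0:
        log.debug("recall undefined (no ground truths); returning 0")
        return 0.0
    return c.tp / denom


def f1(p: float, r: float) -> float:
    """Harmonic mean F1 = 2 P R / (P + R); 0 when both are 0."""
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def accuracy(c) -> float:
    """(TP+TN)/total for binary counts, or trace/total for a K x K matrix."""
    if isinstance(c, ConfusionCounts):
        total = c.tp + c.tn + c.fp + c.fn
        return (c.tp + c.tn) / total if total else 0.0
    m = np.asarray(c, dtype=np.float64)
    total = m.sum()
    return float(np.trace(m) / total) if total else 0.0


def r_squared(y, y_hat) -> float:
    """R² = 1 - Σ(y - ŷ)² / Σ(y - ȳ)²; may be negative, at most 1."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError("actual and predicted series differ in length")
    if y.size < 2:
        raise ValueError("R² needs at least two samples")
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R² undefined: actual counts have zero variance")
    ss_res = float(((y - y_hat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# matching and PR curves
# ---------------------------------------------------------------------------

def match_detections(detections, ground_truths, iou_threshold: float) -> ConfusionCounts:
    """Greedy one-to-one matching for a single image and class.

    ``detections``: sequence of (box, confidence) or Detection objects;
    ``ground_truths``: sequence of boxes.  Returns TP/FP/FN counts (TN is
    not defined for detection and stays 0).
    """
    dets = [(d.box, d.confidence) if hasattr(d, "box") else tuple(d)
            for d in detections]
    gts = list(ground_truths)
    if not dets:
        return ConfusionCounts(fn=len(gts))
    best_ious = [max((box_iou(b, g) for g in gts), default=0.0) for b, _ in dets]
    order = sorted(range(len(dets)),
                   key=lambda i: (-dets[i][1], -best_ious[i], i))
    matched = [False] * len(gts)
    tp = fp = 0
    for i in order:
        box = dets[i][0]
        best_j, best = -1, 0.0
        for j, g in enumerate(gts):
            if matched[j]:
                continue
            v = box_iou(box, g)
            if v > best:
                best, best_j = v, j
        if best_j >= 0 and best >= iou_threshold:
            matched[best_j] = True
            tp += 1
        else:
            fp += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=matched.count(False))


@dataclass
class PRCurve:
    """Precision/recall sweep for one class at one IoU threshold."""
    precisions: np.ndarray
    recalls: np.ndarray
    ap: float
    n_truths: int


def _sweep(class_dets, class_truths, iou_threshold):
    """Confidence sweep over all images of one class.

    class_dets: list over images of [(box, conf), ...];
    class_truths: list over images of [box, ...].
    Returns (tp_flags, confidences, n_truths).
    """
    flags, confs = [], []
    n_truths = sum(len(t) for t in class_truths)
    for dets, gts in zip(class_dets, class_truths):
        if not dets:
            continue
        best_ious = [max((box_iou(b, g) for g in gts), default=0.0)
                     for b, _ in dets]
        order = sorted(range(len(dets)),
                       key=lambda i: (-dets[i][1], -best_ious[i], i))
        matched = [False] * len(gts)
        for i in order:
            box, conf = dets[i]
            best_j, best = -1, 0.0
            for j, g in enumerate(gts):
                if matched[j]:
                    continue
                v = box_iou(box, g)
                if v > best:
                    best, best_j = v, j
            hit = best_j >= 0 and best >= iou_threshold
            if hit:
                matched[best_j] = True
            flags.append(hit)
            confs.append(conf)
    order = np.argsort(-np.asarray(confs, dtype=np.float64), kind="stable") \
        if confs else np.array([], dtype=int)
    flags = np.asarray(flags, dtype=bool)[order]
    return flags, np.asarray(confs)[order] if confs else np.array([]), n_truths


def pr_curve(class_dets, class_truths, iou_threshold: float = 0.5) -> PRCurve:
    flags, _, n_truths = _sweep(class_dets, class_truths, iou_threshold)
    if n_truths == 0:
        return PRCurve(np.array([]), np.array([]), float("nan"), 0)
    if flags.size == 0:
        return PRCurve(np.array([]), np.array([]), 0.0, n_truths)
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    rec = tp_cum / n_truths
    prec = tp_cum / (tp_cum + fp_cum)
    return PRCurve(prec, rec, average_precision(prec, rec), n_truths)


def average_precision(precisions, recalls, method: str = "all_point") -> float:
    """AP = ∫ P(R) dR over the precision envelope.

    ``all_point`` integrates the exact step function; ``interp101``
    evaluates the envelope at 101 equally spaced recall points.
    """
    prec = np.concatenate([[0.0], np.asarray(precisions, dtype=np.float64), [0.0]])
    rec = np.concatenate([[0.0], np.asarray(recalls, dtype=np.float64), [1.0]])
    envelope = np.maximum.accumulate(prec[::-1])[::-1]
    if method == "all_point":
        idx = np.where(rec[1:] != rec[:-1])[0]
        return float(np.sum((rec[idx + 1] - rec[idx]) * envelope[idx + 1]))
    if method == "interp101":
        points = np.linspace(0, 1, 101)
        return float(np.mean(np.interp(points, rec, envelope)))
    raise ValueError(f"unknown AP integration method {method!r}")


def mean_ap(per_class_ap) -> float:
    """Unweighted mean over classes; classes with no truths (NaN AP) are skipped."""
    vals = [a for a in per_class_ap if not np.isnan(a)]
    if not vals:
        log.debug("mAP undefined: no class has ground truths")
        return 0.0
    return float(np.mean(vals))


def _group_by_class(detections, truths, n_classes):
    """Split per-image detections/truths into per-class per-image lists."""
    class_dets = [[] for _ in range(n_classes)]
    class_truths = [[] for _ in range(n_classes)]
    for dets, gts in zip(detections, truths):
        by_cls_d = [[] for _ in range(n_classes)]
        for d in dets:
            cls, box, conf = (d.class_id, d.box, d.confidence) if hasattr(d, "box") \
                else (int(d[0]), tuple(d[1]), float(d[2]))
            by_cls_d[cls].append((box, conf))
        by_cls_t = [[] for _ in range(n_classes)]
        for t in gts:
            by_cls_t[int(t[0])].append(tuple(t[1]))
        for c in range(n_classes):
            class_dets[c].append(by_cls_d[c])
            class_truths[c].append(by_cls_t[c])
    return class_dets, class_truths


def evaluate_label_dirs(pred_dir, truth_dir, n_classes: int = 3,
                        iou_threshold: float = 0.5,
                        conf_threshold: float = 0.25) -> dict:
    """Evaluate a directory of predicted YOLO label files against truth.

    Prediction files may carry 5 columns (class cx cy w h; confidence
    assumed 1.0) or 6 (with a trailing confidence).  Files are paired by
    stem; a missing prediction file means no detections for that image.
    Boxes are compared in normalized coordinates (IoU is scale free).
    """
    from pathlib import Path

    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)
    detections, truths = [], []
    for tf in sorted(truth_dir.glob("*.txt")):
        img_truths, img_dets = [], []
        for ln in tf.read_text().splitlines():
            parts = ln.split()
            if not parts:
                continue
            cls, cx, cy, w, h = int(parts[0]), *map(float, parts[1:5])
            img_truths.append((cls, (cx - w / 2, cy - h / 2,
                                     cx + w / 2, cy + h / 2)))
        pf = pred_dir / tf.name
        if pf.exists():
            for ln in pf.read_text().splitlines():
                parts = ln.split()
                if not parts:
                    continue
                cls, cx, cy, w, h = int(parts[0]), *map(float, parts[1:5])
                conf = float(parts[5]) if len(parts) > 5 else 1.0
                img_dets.append((cls, (cx - w / 2, cy - h / 2,
                                       cx + w / 2, cy + h / 2), conf))
        truths.append(img_truths)
        detections.append(img_dets)
    report = evaluate_detections(detections, truths, n_classes=n_classes,
                                 iou_threshold=iou_threshold,
                                 conf_threshold=conf_threshold)
    y = [len(t) for t in truths]
    y_hat = [sum(1 for d in dets if d[2] >= conf_threshold)
             for dets in detections]
    try:
        report["count_r2"] = r_squared(y, y_hat)
    except ValueError:
        report["count_r2"] = float("nan")
    return report


def evaluate_detections(detections, truths, n_classes: int = 3,
                        iou_threshold: float = 0.5,
                        conf_threshold: float = 0.25) -> dict:
    """Full detection report over a dataset.

    ``detections``: per-image lists of Detection (or (class, box, conf));
    ``truths``: per-image lists of (class, box).  Precision/recall/F1 are
    computed from the confusion counts at ``conf_threshold``; AP/mAP from
    the full confidence sweep.  Classes without ground truths are skipped
    from the mAP averages.
    """
    class_dets, class_truths = _group_by_class(detections, truths, n_classes)
    report = {"per_class": [], "iou_threshold": iou_threshold,
              "conf_threshold": conf_threshold}
    aps50, aps_range = [], []
    agg = ConfusionCounts()
    for c in range(n_classes):
        curve = pr_curve(class_dets[c], class_truths[c], iou_threshold)
        counts = ConfusionCounts()
        for dets, gts in zip(class_dets[c], class_truths[c]):
            counts = counts + match_detections(
                [d for d in dets if d[1] >= conf_threshold], gts, iou_threshold)
        agg = agg + counts
        p, r = precision(counts), recall(counts)
        range_aps = [pr_curve(class_dets[c], class_truths[c], t).ap
                     for t in MAP_RANGE_THRESHOLDS]
        ap_range = (float(np.mean(range_aps))
                    if not any(np.isnan(a) for a in range_aps) else float("nan"))
        report["per_class"].append({
            "class_id": c, "precision": p, "recall": r, "f1": f1(p, r),
            "ap50": curve.ap, "ap50_95": ap_range, "n_truths": curve.n_truths,
        })
        aps50.append(curve.ap)
        aps_range.append(ap_range)
    p, r = precision(agg), recall(agg)
    report["precision"] = p
    report["recall"] = r
    report["f1"] = f1(p, r)
    report["map50"] = mean_ap(aps50)
    report["map50_95"] = mean_ap(aps_range)
    return report
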