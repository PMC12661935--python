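"""Box geometry, confidence scoring and non-maximum suppression.

Pixel coordinates are 0-based with origin at the top-left; boxes are
half-open ``[x1, x2) x [y1, y2)`` so the area of (0,0,2,2) is 4.  YOLO text
labels are center-normalized (class, cx, cy, w, h) in [0,1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CLASS_NAMES = ("bud", "b_flower", "w_flower")


@dataclass
class Detection:
    """One predicted box in absolute pixel coordinates."""
    class_id: int
    box: tuple          # (x1, y1, x2, y2)
    confidence: float

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x2 > x1 and y2 > y1):
            raise ValueError(f"degenerate box {self.box}")
        if not np.isfinite(self.confidence):
            raise ValueError("confidence must be finite")


def confidence_score(pr_object: float, iou: float, pr_class: float) -> float:
    """confidence = Pr(object) * IoU(pred, truth) * Pr(class)."""
    for name, v in (("pr_object", pr_object), ("iou", iou), ("pr_class", pr_class)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return pr_object * iou * pr_class


def box_iou(box_a, box_b) -> float:
    """IoU = area(A ∩ B) / area(A ∪ B) for (x1, y1, x2, y2) boxes."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return float(inter / union)


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N,4) and (M,4) xyxy arrays."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    iw = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0])).clip(0)
    ih = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1])).clip(0)
    inter = iw * ih
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def xywhn_to_xyxy(boxes: np.ndarray, img_w: float, img_h: float) -> np.ndarray:
    """Center-normalized (cx, cy, w, h) -> absolute (x1, y1, x2, y2)."""
    boxes = np.atleast_2d(np.asarray(boxes, dtype=np.float64))
    cx, cy, w, h = boxes[:, 0] * img_w, boxes[:, 1] * img_h, boxes[:, 2] * img_w, boxes[:, 3] * img_h
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=1)


def xyxy_to_xywhn(boxes: np.ndarray, img_w: float, img_h: float) -> np.ndarray:
    """Absolute (x1, y1, x2, y2) -> center-normalized (cx, cy, w, h)."""
    boxes = np.atleast_2d(np.asarray(boxes, dtype=np.float64))
    w = (boxes[:, 2] - boxes[:, 0]) / img_w
    h = (boxes[:, 3] - boxes[:, 1]) / img_h
    cx = (boxes[:, 0] + boxes[:, 2]) / 2 / img_w
    cy = (boxes[:, 1] + boxes[:, 3]) / 2 / img_h
    return np.stack([cx, cy, w, h], axis=1)


def nms(detections, iou_threshold: float = 0.45, confidence_threshold: float = 0.25):
    """Greedy per-class non-maximum suppression.

    Keeps the highest-confidence box, suppresses any same-class box whose
    IoU with a kept box exceeds ``iou_threshold``; boxes below
    ``confidence_threshold`` are discarded first.  Returns a list sorted by
    decreasing confidence; output is always a subset of the input and the
    operation is idempotent.
    """
    if not 0.0 <= iou_threshold <= 1.0 or not 0.0 <= confidence_threshold <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    kept = []
    dets = [d for d in detections if d.confidence >= confidence_threshold]
    for cls in sorted({d.class_id for d in dets}):
        cand = sorted((d for d in dets if d.class_id == cls),
                      key=lambda d: -d.confidence)
        cls_kept = []
        for d in cand:
            if all(box_iou(d.box, k.box) <= iou_threshold for k in cls_kept):
                cls_kept.append(d)
        kept.extend(cls_kept)
    kept.sort(key=lambda d: -d.confidence)
    return kept
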