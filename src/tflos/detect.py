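"""Inference: decode, suppress, count, tile.

``detect_and_count`` runs the detector over a batch of images and writes
one CSV row per input image (``image,bud,b_flower,w_flower,total``), the
direct-counting output of the model.  ``tile_image`` crops a full-frame
capture into its 2x2 quadrants with label re-normalization.
"""

from __future__ import annotations

import csv
import logging

import numpy as np
from PIL import Image

from . import nn
from .boxes import Detection, nms
from .model import decode_head
from .records import CountRecord

log = logging.getLogger(__name__)


def _prepare(image: np.ndarray, input_size: int):
    """uint8 (H, W, 3) -> float CHW at the model input size."""
    h, w = image.shape[:2]
    if (h, w) != (input_size, input_size):
        image = np.asarray(Image.fromarray(image).resize(
            (input_size, input_size), Image.BILINEAR))
    x = image.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
    return x, (w / input_size, h / input_size)


def _raw_detections(model, image, conf_threshold):
    cfg = model.cfg
    x, (sx, sy) = _prepare(image, cfg.input_size)
    model.eval()
    with nn.no_grad():
        preds = model(x)
    cand = []
    for p, anc, stride in zip(preds, cfg.anchors, cfg.strides):
        boxes, obj, cls = decode_head(p, anc, stride, cfg.n_classes)
        conf = obj[0][:, None] * cls[0]            # Pr(object) * Pr(class)
        best_cls = conf.argmax(axis=1)
        best_conf = conf[np.arange(len(best_cls)), best_cls]
        keep = best_conf >= conf_threshold
        for b, c, s in zip(boxes[0][keep], best_cls[keep], best_conf[keep]):
            x1, y1, x2, y2 = b
            x1, x2 = sorted((float(x1) * sx, float(x2) * sx))
            y1, y2 = sorted((float(y1) * sy, float(y2) * sy))
            if x2 - x1 < 1e-3 or y2 - y1 < 1e-3:
                continue
            cand.append(Detection(int(c), (x1, y1, x2, y2), float(s)))
    return cand


def detect_image(model, image: np.ndarray, conf_threshold: float = 0.25,
                 iou_threshold: float = 0.45, tta: bool = False) -> list:
    """Detections for one uint8 (H, W, 3) image, in its own pixel frame.

    ``tta=True`` adds horizontal-flip test-time augmentation: the image is
    also run mirrored, the mirrored boxes are flipped back, and the union
    passes through NMS — an inference-time ensemble that smooths
    localization noise at twice the compute.
    """
    cand = _raw_detections(model, image, conf_threshold)
    if tta:
        w = image.shape[1]
        for d in _raw_detections(model, image[:, ::-1].copy(), conf_threshold):
            x1, y1, x2, y2 = d.box
            cand.append(Detection(d.class_id, (w - x2, y1, w - x1, y2),
                                  d.confidence))
    return nms(cand, iou_threshold=iou_threshold,
               confidence_threshold=conf_threshold)


def count_detections(detections, n_classes: int = 3):
    """Class-wise cardinality of a detection list."""
    counts = [0] * n_classes
    for d in detections:
        counts[d.class_id] += 1
    return tuple(counts)


def detect_and_count(images, model=None, conf_threshold: float = 0.25,
                     iou_threshold: float = 0.45, csv_path=None,
                     detections_override=None) -> list:
    """One CountRecord per input image, in input order.

    ``images``: list of (image_id, ndarray-or-path).  Unreadable images
    produce a record with -0 counts and an error log entry, and the CSV row
    notes the error.  ``detections_override`` (list of detection lists)
    bypasses the network — counting is then pure class-wise cardinality,
    used for testing and for externally produced detections.
    """
    records, rows = [], []
    for i, (image_id, src) in enumerate(images):
        try:
            if detections_override is not None:
                dets = detections_override[i]
            else:
                img = src if isinstance(src, np.ndarray) else \
                    np.asarray(Image.open(src).convert("RGB"))
                dets = detect_image(model, img, conf_threshold, iou_threshold)
        except Exception as exc:   # unreadable image: log and continue
            log.error("failed to process %s: %s", image_id, exc)
            rows.append({"image": image_id, "bud": "", "b_flower": "",
                         "w_flower": "", "total": "", "error": str(exc)})
            continue
        nb, nf, nw = count_detections(dets)
        rec = CountRecord(image_id=str(image_id), n_bud=nb, n_bloom=nf,
                          n_wither=nw)
        records.append(rec)
        rows.append({"image": image_id, "bud": nb, "b_flower": nf,
                     "w_flower": nw, "total": nb + nf + nw, "error": ""})
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["image", "bud", "b_flower", "w_flower",
                                "total", "error"])
            writer.writeheader()
            writer.writerows(rows)
    return records


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

FULL_FRAME = (3280, 2464)       # capture resolution (w, h)
TILE_SIZE = (1640, 1232)


def tile_image(image: np.ndarray, labels=(), min_visible_fraction: float = 0.25,
               expected_size=FULL_FRAME, on_size_mismatch: str = "error"):
    """Crop into non-overlapping 2x2 quadrants, row-major.

    Labels (class, cx, cy, w, h normalized to the full frame) are clipped
    to each quadrant and re-normalized; a clipped fragment whose area falls
    below ``min_visible_fraction`` of the original box is dropped.
    ``on_size_mismatch``: 'error' rejects inputs that are not
    ``expected_size``; 'resize' rescales them first.
    """
    h, w = image.shape[:2]
    if expected_size is not None and (w, h) != tuple(expected_size):
        if on_size_mismatch == "resize":
            image = np.asarray(Image.fromarray(image).resize(
                expected_size, Image.BILINEAR))
            h, w = image.shape[:2]
        else:
            raise ValueError(f"expected a {expected_size[0]}x{expected_size[1]} "
                             f"image, got {w}x{h}")
    th, tw = h // 2, w // 2
    tiles = []
    for q in range(4):
        qr, qc = divmod(q, 2)
        sub = image[qr * th:(qr + 1) * th, qc * tw:(qc + 1) * tw]
        x0, y0 = qc * tw, qr * th
        sub_labels = []
        for cls, cx, cy, bw, bh in labels:
            x1, y1 = (cx - bw / 2) * w, (cy - bh / 2) * h
            x2, y2 = (cx + bw / 2) * w, (cy + bh / 2) * h
            ix1, iy1 = max(x1, x0), max(y1, y0)
            ix2, iy2 = min(x2, x0 + tw), min(y2, y0 + th)
            if ix2 <= ix1 or iy2 <= iy1:
                continue
            frac = (ix2 - ix1) * (iy2 - iy1) / ((x2 - x1) * (y2 - y1))
            if frac < min_visible_fraction:
                continue
            sub_labels.append((cls,
                               ((ix1 + ix2) / 2 - x0) / tw,
                               ((iy1 + iy2) / 2 - y0) / th,
                               (ix2 - ix1) / tw, (iy2 - iy1) / th))
        tiles.append((sub, sub_labels))
    return tiles
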