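"""Training-time image augmentations: HSV jitter, rotation, mosaic.

Each transform returns both the image and the transformed labels so that
label-image consistency is preserved (rotated boxes become the axis-aligned
bounding box of the rotated corners).  All randomness comes from an
explicit generator.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from .boxes import xywhn_to_xyxy, xyxy_to_xywhn


def hsv_jitter(image: np.ndarray, rng: np.random.Generator,
               h_gain=0.015, s_gain=0.7, v_gain=0.4):
    """Random hue/saturation/value shift; labels are unaffected."""
    im = Image.fromarray(image).convert("HSV")
    arr = np.asarray(im, dtype=np.float32)
    gains = rng.uniform(-1, 1, 3) * (h_gain, s_gain, v_gain) + 1
    arr[..., 0] = (arr[..., 0] * gains[0]) % 256
    arr[..., 1] = np.clip(arr[..., 1] * gains[1], 0, 255)
    arr[..., 2] = np.clip(arr[..., 2] * gains[2], 0, 255)
    out = Image.fromarray(arr.astype(np.uint8), "HSV").convert("RGB")
    return np.asarray(out)


def rotate(image: np.ndarray, labels, angle_deg: float):
    """Rotate about the image center; boxes become the bbox of their
    rotated corners, clipped to the frame."""
    h, w = image.shape[:2]
    im = Image.fromarray(image).rotate(angle_deg, resample=Image.BILINEAR,
                                       fillcolor=(40, 70, 35))
    out_labels = []
    if labels:
        theta = np.deg2rad(-angle_deg)   # PIL rotates counter-clockwise
        c, s = np.cos(theta), np.sin(theta)
        cx0, cy0 = w / 2, h / 2
        boxes = xywhn_to_xyxy(np.array([l[1:5] for l in labels]), w, h)
        for (x1, y1, x2, y2), lab in zip(boxes, labels):
            corners = np.array([[x1, y1], [x2, y1], [x1, y2], [x2, y2]])
            rel = corners - (cx0, cy0)
            rot = rel @ np.array([[c, -s], [s, c]]).T + (cx0, cy0)
            nx1, ny1 = rot.min(axis=0)
            nx2, ny2 = rot.max(axis=0)
            nx1, nx2 = np.clip([nx1, nx2], 0, w)
            ny1, ny2 = np.clip([ny1, ny2], 0, h)
            if nx2 - nx1 < 2 or ny2 - ny1 < 2:
                continue
            cxn, cyn, wn, hn = xyxy_to_xywhn(
                np.array([[nx1, ny1, nx2, ny2]]), w, h)[0]
            out_labels.append((lab[0], cxn, cyn, wn, hn))
    return np.asarray(im), out_labels


def mosaic(images, labels_list, rng: np.random.Generator):
    """Combine four images into a 2x2 mosaic of the same final size.

    Each source is resized to a quadrant; labels are rescaled and shifted
    into their quadrant.
    """
    assert len(images) == 4
    size = images[0].shape[0]
    half = size // 2
    canvas = np.zeros((size, size, 3), np.uint8)
    out_labels = []
    for q, (img, labels) in enumerate(zip(images, labels_list)):
        qr, qc = divmod(q, 2)
        tile = np.asarray(Image.fromarray(img).resize((half, half),
                                                      Image.BILINEAR))
        canvas[qr * half:(qr + 1) * half, qc * half:(qc + 1) * half] = tile
        for cls, cx, cy, w_, h_ in labels:
            out_labels.append((cls, (cx * half + qc * half) / size,
                               (cy * half + qr * half) / size,
                               w_ * half / size, h_ * half / size))
    return canvas, out_labels
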