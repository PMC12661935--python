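"""Seeded synthetic tea-flower scenes with YOLO labels.

Scenes emulate the difficulties of field imagery of flowering tea rows
without photorealism: dense small targets on a cluttered green canopy,
three visually distinct object classes (unopened buds, white blooming
flowers with a yellow core, brown withered flowers), partial occlusion by
leaf and branch primitives, front/back lighting and bright light-spot
artifacts.  Class prevalence defaults to 57% bud / 25% blooming / 18%
withered, the imbalance typical of a flowering season.

Every scene is a pure function of its :class:`SceneSpec` (including the
seed): the same spec yields a bit-identical image and byte-identical label
file on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..yolo_io import (SPLITS, dataset_paths, largest_remainder_split,
                       make_dataset_tree, write_image, write_labels)

CLASS_BUD, CLASS_BLOOM, CLASS_WITHER = 0, 1, 2

#: object size ranges in pixels (long axis), per class
SIZE_RANGES = {CLASS_BUD: (8, 20), CLASS_BLOOM: (15, 40), CLASS_WITHER: (10, 30)}


class PlacementError(RuntimeError):
    """Raised when non-degenerate object placement fails repeatedly."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""
    image_size: int = 640
    n_objects: int = 20
    class_mix: tuple = (0.57, 0.25, 0.18)
    occlusion_rate: float = 0.3
    lighting: str = "frontlight"
    light_spot_rate: float = 0.1
    min_visible_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or len(self.class_mix) != 3:
            raise ValueError(f"class_mix must be 3 probabilities summing to 1, "
                             f"got {self.class_mix}")
        if not 0.0 < self.min_visible_fraction <= 1.0:
            raise ValueError("min_visible_fraction must lie in (0, 1]")
        if self.lighting not in ("frontlight", "backlight"):
            raise ValueError(f"unknown lighting {self.lighting!r}")
        if self.n_objects < 0:
            raise ValueError("n_objects must be non-negative")


# ---------------------------------------------------------------------------
# low-level painters (all operate on float32 canvases in [0, 255])
# ---------------------------------------------------------------------------

def _ellipse_mask(size, cx, cy, a, b, theta):
    """Boolean mask of a rotated ellipse, computed on the full grid."""
    y, x = np.mgrid[0:size, 0:size]
    ct, st = np.cos(theta), np.sin(theta)
    u = (x - cx) * ct + (y - cy) * st
    v = -(x - cx) * st + (y - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _paint(img, mask, color, alpha=1.0):
    img[mask] = (1 - alpha) * img[mask] + alpha * np.asarray(color, np.float32)


def _line_mask(size, p1, p2, thickness):
    y, x = np.mgrid[0:size, 0:size]
    p1 = np.asarray(p1, np.float64)
    d = np.asarray(p2, np.float64) - p1
    L2 = max(float(d @ d), 1e-9)
    t = ((x - p1[0]) * d[0] + (y - p1[1]) * d[1]) / L2
    t = np.clip(t, 0, 1)
    dist2 = (x - (p1[0] + t * d[0])) ** 2 + (y - (p1[1] + t * d[1])) ** 2
    return dist2 <= (thickness / 2.0) ** 2


def _background(size, rng):
    """Layered canopy: green gradient, leaf ellipses, dark branch strokes."""
    base = np.empty((size, size, 3), np.float32)
    grad = np.linspace(0.85, 1.1, size, dtype=np.float32)[:, None]
    base[..., 0] = 46 * grad
    base[..., 1] = 82 * grad
    base[..., 2] = 38 * grad
    for _ in range(max(6, size // 40)):
        cx, cy = rng.uniform(0, size, 2)
        a, b = rng.uniform(size * 0.05, size * 0.25, 2)
        shade = rng.uniform(0.6, 1.4)
        color = np.clip(np.array([40, 90, 35]) * shade, 0, 140)
        _paint(base, _ellipse_mask(size, cx, cy, a, b, rng.uniform(0, np.pi)),
               color, alpha=rng.uniform(0.3, 0.7))
    for _ in range(max(2, size // 120)):
        p1 = rng.uniform(0, size, 2)
        p2 = p1 + rng.uniform(-size * 0.6, size * 0.6, 2)
        _paint(base, _line_mask(size, p1, p2, rng.uniform(2, 5)),
               (52, 38, 24), alpha=0.85)
    return base


def _draw_flower(img, cls, cx, cy, long_axis, rng):
    """Paint one object; returns its boolean mask (its own pixels)."""
    size = img.shape[0]
    mask = np.zeros(img.shape[:2], bool)
    if cls == CLASS_BUD:
        a = long_axis / 2.0
        b = a * rng.uniform(0.6, 0.85)
        th = rng.uniform(0, np.pi)
        m = _ellipse_mask(size, cx, cy, a, b, th)
        _paint(img, m, (224, 222, 196))
        mask |= m
    elif cls == CLASS_BLOOM:
        r = long_axis / 2.0
        n_petals = rng.integers(5, 8)
        phase = rng.uniform(0, 2 * np.pi)
        for i in range(n_petals):
            ang = phase + 2 * np.pi * i / n_petals
            pcx = cx + 0.45 * r * np.cos(ang)
            pcy = cy + 0.45 * r * np.sin(ang)
            m = _ellipse_mask(size, pcx, pcy, 0.55 * r, 0.32 * r, ang)
            _paint(img, m, (246, 246, 240))
            mask |= m
        core = _ellipse_mask(size, cx, cy, 0.28 * r, 0.28 * r, 0.0)
        _paint(img, core, (236, 206, 64))
        mask |= core
    else:
        r = long_axis / 2.0
        for _ in range(3):
            ocx = cx + rng.uniform(-0.3, 0.3) * r
            ocy = cy + rng.uniform(-0.3, 0.3) * r
            m = _ellipse_mask(size, ocx, ocy, rng.uniform(0.5, 0.8) * r,
                              rng.uniform(0.35, 0.65) * r, rng.uniform(0, np.pi))
            _paint(img, m, (128 + rng.uniform(-20, 20),
                            88 + rng.uniform(-15, 15), 42))
            mask |= m
    return mask


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def generate_scene(spec: SceneSpec, max_attempts_per_object: int = 60):
    """Render one scene.

    Returns ``(image, boxes, manifest)``: an (S, S, 3) uint8 image, labeled
    boxes as (class_id, cx, cy, w, h) normalized to [0, 1], and a manifest
    dict with the true pre-occlusion per-class counts.  Objects whose
    visible fraction after occluder painting falls below
    ``spec.min_visible_fraction`` are omitted from the labels but still
    counted in the manifest.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    size = spec.image_size
    img = _background(size, rng)

    # -- place and draw flowers ------------------------------------------
    placed = []          # (cls, bbox xyxy) for overlap control
    masks, classes = [], []
    true_counts = [0, 0, 0]
    for _ in range(spec.n_objects):
        cls = int(rng.choice(3, p=spec.class_mix))
        lo, hi = SIZE_RANGES[cls]
        for attempt in range(max_attempts_per_object):
            long_axis = rng.uniform(lo, hi)
            margin = long_axis / 2 + 1
            if size <= 2 * margin:
                raise PlacementError(
                    f"objects of size {long_axis:.0f}px do not fit a "
                    f"{size}px image")
            cx, cy = rng.uniform(margin, size - margin, 2)
            half = long_axis / 2
            cand = (cx - half, cy - half, cx + half, cy + half)
            crowded = any(_box_overlap(cand, p) > 0.35 for p in placed)
            if not crowded:
                break
        else:
            raise PlacementError(
                f"could not place object {len(placed) + 1}/{spec.n_objects} "
                f"after {max_attempts_per_object} attempts")
        m = _draw_flower(img, cls, cx, cy, long_axis, rng)
        placed.append(cand)
        masks.append(m)
        classes.append(cls)
        true_counts[cls] += 1

    # -- occluders --------------------------------------------------------
    occluder = np.zeros((size, size), bool)
    for i, m in enumerate(masks):
        if rng.uniform() >= spec.occlusion_rate or not m.any():
            continue
        ys, xs = np.nonzero(m)
        x1, x2 = xs.min(), xs.max()
        y1, y2 = ys.min(), ys.max()
        ocx = rng.uniform(x1, x2)
        ocy = rng.uniform(y1, y2)
        extent = max(x2 - x1, y2 - y1)
        if rng.uniform() < 0.6:     # leaf
            om = _ellipse_mask(size, ocx, ocy, rng.uniform(0.4, 0.9) * extent,
                               rng.uniform(0.25, 0.6) * extent,
                               rng.uniform(0, np.pi))
            _paint(img, om, (44, 96, 40))
        else:                       # branch
            ang = rng.uniform(0, np.pi)
            L = extent * rng.uniform(1.0, 2.0)
            p1 = (ocx - L * np.cos(ang), ocy - L * np.sin(ang))
            p2 = (ocx + L * np.cos(ang), ocy + L * np.sin(ang))
            om = _line_mask(size, p1, p2, rng.uniform(3, max(4, extent * 0.3)))
            _paint(img, om, (52, 38, 24))
        occluder |= om

    # -- lighting and artifacts ------------------------------------------
    if spec.lighting == "backlight":
        img *= 0.6
        mean = img.mean()
        img = 0.75 * (img - mean) + mean
    if rng.uniform() < spec.light_spot_rate:
        for _ in range(rng.integers(1, 4)):
            scx, scy = rng.uniform(0, size, 2)
            sm = _ellipse_mask(size, scx, scy, rng.uniform(size * 0.03, size * 0.1),
                               rng.uniform(size * 0.03, size * 0.1),
                               rng.uniform(0, np.pi))
            _paint(img, sm, (255, 255, 250), alpha=0.5)

    # -- labels -----------------------------------------------------------
    boxes = []
    for cls, m in zip(classes, masks):
        if not m.any():
            continue
        visible = (m & ~occluder).sum() / m.sum()
        if visible < spec.min_visible_fraction:
            continue
        ys, xs = np.nonzero(m)
        x1, x2 = xs.min(), xs.max() + 1
        y1, y2 = ys.min(), ys.max() + 1
        boxes.append((cls, (x1 + x2) / 2 / size, (y1 + y2) / 2 / size,
                      (x2 - x1) / size, (y2 - y1) / size))

    manifest = {"n_bud": true_counts[0], "n_bloom": true_counts[1],
                "n_wither": true_counts[2]}
    return np.clip(img, 0, 255).astype(np.uint8), boxes, manifest


def _box_overlap(a, b) -> float:
    iw = min(a[2], b[2]) - max(a[0], b[0])
    ih = min(a[3], b[3]) - max(a[1], b[1])
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = ((a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return inter / union


def generate_dataset(spec: SceneSpec, n_images: int, out_dir,
                     split=(0.6, 0.2, 0.2), n_objects_range=None) -> pd.DataFrame:
    """Write a full dataset tree and return its manifest.

    Per-image seeds derive from ``spec.seed`` so the dataset is reproducible
    as a whole; ``n_objects_range=(lo, hi)`` draws a per-image object count
    uniformly (inclusive), which gives the count spread needed for
    regression checks.  Split sizes follow largest-remainder rounding of
    the requested fractions.
    """
    make_dataset_tree(out_dir)
    counts = largest_remainder_split(n_images, split)
    split_of = [s for s, c in zip(SPLITS, counts) for _ in range(c)]
    master = np.random.Generator(np.random.PCG64(spec.seed))
    rows = []
    for i in range(n_images):
        n_obj = spec.n_objects if n_objects_range is None else \
            int(master.integers(n_objects_range[0], n_objects_range[1] + 1))
        sub = replace(spec, n_objects=n_obj, seed=int(master.integers(2 ** 31)))
        img, boxes, manifest = generate_scene(sub)
        name = f"scene_{i:05d}"
        img_dir, lbl_dir = dataset_paths(out_dir, split_of[i])
        write_image(img_dir / f"{name}.png", img)
        write_labels(lbl_dir / f"{name}.txt", boxes)
        rows.append({"image": name, "split": split_of[i], **manifest})
    df = pd.DataFrame(rows)
    df.to_csv(f"{out_dir}/manifest.csv", index=False)
    return df
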