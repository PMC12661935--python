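"""Reading and writing YOLO-format annotations and dataset trees.

One text file per image, one line per object: ``class_id cx cy w h`` with
center-normalized coordinates written as 6-decimal fixed point.  A dataset
is a directory tree ``images/{train,val,test}/*.png`` plus
``labels/{train,val,test}/*.txt`` and a ``manifest.csv`` with the true
per-class object counts of every image.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

SPLITS = ("train", "val", "test")


def write_labels(path, boxes) -> None:
    """Write (class_id, cx, cy, w, h) rows; coordinates to 6 decimals."""
    lines = []
    for b in boxes:
        cls, cx, cy, w, h = int(b[0]), *[float(v) for v in b[1:5]]
        for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1] in {path}")
        lines.append(f"{cls} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_labels(path) -> list:
    """Read label rows as (class_id, cx, cy, w, h) tuples."""
    out = []
    text = Path(path).read_text()
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln:
            continue
        parts = ln.split()
        if len(parts) != 5:
            raise ValueError(f"malformed label line {ln!r} in {path}")
        out.append((int(parts[0]), *[float(p) for p in parts[1:]]))
    return out


def write_image(path, image: np.ndarray) -> None:
    """Save an (H, W, 3) uint8 array as PNG."""
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path, format="PNG")


def read_image(path) -> np.ndarray:
    """Load an image file as an (H, W, 3) uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def dataset_paths(root, split):
    root = Path(root)
    return root / "images" / split, root / "labels" / split


def make_dataset_tree(root):
    for split in SPLITS:
        for d in dataset_paths(root, split):
            d.mkdir(parents=True, exist_ok=True)


def list_split(root, split):
    """Sorted (image_path, label_path) pairs of one split."""
    img_dir, lbl_dir = dataset_paths(root, split)
    pairs = []
    if not img_dir.is_dir():
        return pairs
    for img in sorted(img_dir.iterdir()):
        if img.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        pairs.append((img, lbl_dir / (img.stem + ".txt")))
    return pairs


def largest_remainder_split(n: int, fractions) -> list:
    """Assign n items to len(fractions) groups by largest remainder.

    Exact when n * fraction is integral (e.g. 100 at 6:2:2 -> 60/20/20);
    otherwise leftover items go to the groups with the largest fractional
    parts, ties to the earlier group.
    """
    fractions = [float(f) for f in fractions]
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {fractions}")
    raw = [n * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts
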