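"""Images, masks, polygon annotations, manifests and dataset splits.

Conventions: coordinates are 0-based, row-major, origin at the top-left;
masks are {0,1} uint8 in memory and 0/255 single-channel PNG on disk.
Annotation documents follow the LabelMe JSON layout (``imageHeight``,
``imageWidth``, ``shapes: [{label, points}]`` with points as (x, y) pixel
coordinates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from PIL import Image
from shapely.geometry import Polygon as _Polygon

__all__ = [
    "AnnotationDoc",
    "DatasetSplit",
    "load_annotation",
    "save_annotation",
    "rasterize_annotation",
    "split_dataset",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]


# ---------------------------------------------------------------------------
# images and masks

def read_image(path) -> np.ndarray:
    """Read an RGB image (PNG/BMP/...) as (H, W, 3) uint8."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_mask(path) -> np.ndarray:
    """Read a 0/255 mask file as a {0,1} uint8 array."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(arr, mode="L").save(path)


# ---------------------------------------------------------------------------
# polygon annotations

@dataclass
class AnnotationDoc:
    """Polygon annotations for one image."""

    image_height: int
    image_width: int
    shapes: list = field(default_factory=list)  # [(label, (N,2) float xy)]

    def validate(self) -> None:
        for i, (_, pts) in enumerate(self.shapes):
            pts = np.asarray(pts, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
                raise ValueError(f"polygon {i} malformed: needs >= 3 (x, y) vertices")
            if (pts[:, 0] < 0).any() or (pts[:, 0] > self.image_width).any() \
                    or (pts[:, 1] < 0).any() or (pts[:, 1] > self.image_height).any():
                raise ValueError(f"polygon {i} has vertices outside the image")


def load_annotation(path) -> AnnotationDoc:
    with open(path) as fh:
        doc = json.load(fh)
    shapes = [(s.get("label", ""), np.asarray(s["points"], dtype=float))
              for s in doc.get("shapes", [])]
    return AnnotationDoc(image_height=int(doc["imageHeight"]),
                         image_width=int(doc["imageWidth"]), shapes=shapes)


def save_annotation(path, doc: AnnotationDoc) -> None:
    payload = {
        "imageHeight": doc.image_height,
        "imageWidth": doc.image_width,
        "shapes": [{"label": label, "points": np.asarray(pts, float).tolist(),
                    "shape_type": "polygon"} for label, pts in doc.shapes],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def rasterize_annotation(doc: AnnotationDoc, width: int | None = None,
                         height: int | None = None) -> np.ndarray:
    """Convert polygon annotations to a {0,1} mask.

    A pixel (row r, col c) is foreground iff its centre (c + 0.5, r + 0.5)
    lies inside or on the boundary of any polygon.
    """
    width = doc.image_width if width is None else width
    height = doc.image_height if height is None else height
    doc.validate()
    mask = np.zeros((height, width), dtype=np.uint8)
    if not doc.shapes:
        return mask
    cx, cy = np.meshgrid(np.arange(width) + 0.5, np.arange(height) + 0.5)
    for i, (_, pts) in enumerate(doc.shapes):
        poly = _Polygon(np.asarray(pts, dtype=float))
        x0, y0, x1, y1 = poly.bounds
        c0, c1 = max(int(x0 - 1), 0), min(int(x1 + 2), width)
        r0, r1 = max(int(y0 - 1), 0), min(int(y1 + 2), height)
        if c0 >= c1 or r0 >= r1:
            continue
        inside = shapely.intersects_xy(poly, cx[r0:r1, c0:c1], cy[r0:r1, c0:c1])
        mask[r0:r1, c0:c1] |= inside.astype(np.uint8)
    return mask


# ---------------------------------------------------------------------------
# dataset splitting

@dataclass(frozen=True)
class DatasetSplit:
    train: tuple
    validation: tuple
    fraction: float
    seed: int


def split_dataset(items, fraction: float = 0.8, seed: int = 0,
                  groups=None) -> DatasetSplit:
    """Random train/validation split: shuffle, first floor(fraction*n) train.

    With ``groups`` (one hashable label per item, e.g. the source image of
    each tile), whole groups are shuffled and assigned together so that no
    group straddles the split — the leakage-aware alternative to the
    default random-by-item split.
    """
    items = list(items)
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if groups is None:
        order = rng.permutation(n)
        n_train = int(fraction * n)
        train_idx, val_idx = order[:n_train], order[n_train:]
    else:
        groups = list(groups)
        if len(groups) != n:
            raise ValueError("need one group label per item")
        unique = sorted(set(groups), key=repr)
        if len(unique) < 2:
            raise ValueError("need at least 2 groups to split by group")
        g_order = rng.permutation(len(unique))
        n_train_groups = max(1, min(len(unique) - 1,
                                    int(round(fraction * len(unique)))))
        train_groups = {unique[i] for i in g_order[:n_train_groups]}
        train_idx = [i for i, g in enumerate(groups) if g in train_groups]
        val_idx = [i for i, g in enumerate(groups) if g not in train_groups]
    train = tuple(items[i] for i in train_idx)
    val = tuple(items[i] for i in val_idx)
    return DatasetSplit(train=train, validation=val, fraction=fraction, seed=seed)
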