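"""Context-expanded tiling of full leaf images and seam-free stitching.

A full image is divided into non-overlapping 100x100 *cores*; for
prediction, each core is presented to the network inside a 120x120
*context window* (a 10-px margin on every side), and the margin of each
predicted tile is discarded before the cores are reassembled. This removes
the stripe artefacts that appear when tiles are predicted and stitched
edge-to-edge: every stitched pixel was predicted with at least 10 px of
real context around it. Context beyond the image border (and any
right/bottom remainder when the image size is not a multiple of the tile
size) is reflection-padded so dark zero-borders cannot masquerade as
glands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TileGrid", "crop_tiles", "stitch_tiles"]


@dataclass(frozen=True)
class TileGrid:
    """Placement of context-expanded tiles over an image."""

    image_height: int
    image_width: int
    tile_size: int = 100
    context_size: int = 120

    def __post_init__(self):
        if self.context_size < self.tile_size:
            raise ValueError("context_size must be >= tile_size")
        if (self.context_size - self.tile_size) % 2:
            raise ValueError("context margin must be symmetric "
                             "(context_size - tile_size even)")
        if self.image_height < self.tile_size or self.image_width < self.tile_size:
            raise ValueError(
                f"image {self.image_width}x{self.image_height} smaller than "
                f"tile size {self.tile_size}")

    @property
    def margin(self) -> int:
        return (self.context_size - self.tile_size) // 2

    @property
    def rows(self) -> int:
        return -(-self.image_height // self.tile_size)

    @property
    def cols(self) -> int:
        return -(-self.image_width // self.tile_size)

    @property
    def n_tiles(self) -> int:
        return self.rows * self.cols

    def tiles(self):
        """Yield (row, col, core_y, core_x) for every tile core."""
        for r in range(self.rows):
            for c in range(self.cols):
                yield r, c, r * self.tile_size, c * self.tile_size

    def to_json(self) -> str:
        return json.dumps({
            "image_height": self.image_height, "image_width": self.image_width,
            "tile_size": self.tile_size, "context_size": self.context_size,
            "margin": self.margin, "rows": self.rows, "cols": self.cols,
        })


def _pad_to_grid(image: np.ndarray, grid: TileGrid) -> np.ndarray:
    """Reflection-pad by the context margin plus any right/bottom remainder."""
    m = grid.margin
    pad_b = grid.rows * grid.tile_size - grid.image_height + m
    pad_r = grid.cols * grid.tile_size - grid.image_width + m
    pad = [(m, pad_b), (m, pad_r)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad, mode="reflect")


def crop_tiles(image: np.ndarray, grid: TileGrid) -> np.ndarray:
    """Cut an image into context windows, one per grid core.

    Returns an array of shape (n_tiles, context, context[, channels]) in
    row-major core order.
    """
    image = np.asarray(image)
    if image.shape[0] != grid.image_height or image.shape[1] != grid.image_width:
        raise ValueError(
            f"image shape {image.shape[:2]} does not match grid "
            f"{(grid.image_height, grid.image_width)}")
    padded = _pad_to_grid(image, grid)
    s = grid.context_size
    tiles = np.empty((grid.n_tiles,) + (s, s) + image.shape[2:], dtype=image.dtype)
    for i, (_, _, y, x) in enumerate(grid.tiles()):
        tiles[i] = padded[y:y + s, x:x + s]
    return tiles


def stitch_tiles(tile_masks, grid: TileGrid) -> np.ndarray:
    """Reassemble per-tile predictions into a full-image mask.

    Each tile prediction must be context-sized; its margin is trimmed and
    the central core placed at the core's position. The output has exactly
    the grid's image dimensions (any reflection padding is cropped away),
    and ``stitch_tiles(crop_tiles(m, g), g) == m`` for any mask ``m``.
    """
    tile_masks = np.asarray(tile_masks)
    if len(tile_masks) != grid.n_tiles:
        raise ValueError(
            f"got {len(tile_masks)} tiles for a grid of {grid.n_tiles}")
    s, m, t = grid.context_size, grid.margin, grid.tile_size
    if tile_masks.shape[1:3] != (s, s):
        raise ValueError(f"tiles must be {s}x{s}, got {tile_masks.shape[1:3]}")
    full_h, full_w = grid.rows * t, grid.cols * t
    out = np.empty((full_h, full_w) + tile_masks.shape[3:], dtype=tile_masks.dtype)
    for i, (_, _, y, x) in enumerate(grid.tiles()):
        out[y:y + t, x:x + t] = tile_masks[i, m:m + t, m:m + t]
    return out[:grid.image_height, :grid.image_width]
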