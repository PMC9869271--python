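"""Whole-image prediction: tile -> forward -> binarise -> stitch -> count."""

from __future__ import annotations

import numpy as np

from . import postprocess as _post
from . import tiling as _tiling
from .network import IppNet, binarize

__all__ = ["segment_image", "count_image", "per_tile_counts"]


def segment_image(net: IppNet, image: np.ndarray, tile_size: int = 100,
                  tau: float = 0.5, batch_size: int = 8) -> np.ndarray:
    """Segment a full RGB image into a {0,1} gland mask.

    The image is cut into ``tile_size`` cores with context windows matching
    the network's input size; each predicted window is thresholded at
    ``tau`` and the margins are trimmed during stitching.
    """
    image = np.asarray(image)
    grid = _tiling.TileGrid(image.shape[0], image.shape[1],
                            tile_size=tile_size,
                            context_size=net.spec.input_size)
    tiles = _tiling.crop_tiles(image, grid)
    preds = np.empty(tiles.shape[:3], dtype=np.uint8)
    for i in range(0, len(tiles), batch_size):
        x = tiles[i:i + batch_size].astype(np.float32) / 255.0
        preds[i:i + batch_size] = binarize(net.forward(x, train=False), tau)
    return _tiling.stitch_tiles(preds, grid)


def count_image(net: IppNet, image: np.ndarray,
                filter_config: _post.FilterConfig | None = None,
                tile_size: int = 100, tau: float = 0.5) -> tuple:
    """Segment and count a full image; returns (count, stitched mask)."""
    mask = segment_image(net, image, tile_size=tile_size, tau=tau)
    return _post.count_glands(mask, filter_config), mask


def per_tile_counts(mask: np.ndarray, tile_size: int = 100,
                    filter_config: _post.FilterConfig | None = None) -> np.ndarray:
    """Gland count on every ``tile_size`` core of a full mask (row-major).

    Used for density stratification and counting-agreement studies; note
    whole-image counts should be taken on the full stitched mask instead,
    so glands straddling core boundaries are not double-counted.
    """
    mask = np.asarray(mask)
    grid = _tiling.TileGrid(mask.shape[0], mask.shape[1], tile_size=tile_size,
                            context_size=tile_size)
    counts = np.empty(grid.n_tiles, dtype=int)
    t = tile_size
    for i, (_, _, y, x) in enumerate(grid.tiles()):
        counts[i] = _post.count_glands(mask[y:y + t, x:x + t], filter_config)
    return counts
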