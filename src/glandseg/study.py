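"""Desk-scale end-to-end study on synthetic low-density scenes.

This is the package's self-contained benchmark: generate level-1 scenes
(with vein confounders), train a reduced network for a few epochs, and
measure (a) validation-tile F1 of the segmentation and (b) the squared
Pearson correlation between per-tile predicted and reference gland counts
on held-out scenes. Problem sizes are chosen so the whole study runs in a
few minutes on one CPU core: 200 training and 50 held-out context tiles,
a base width of 8 channels, and 5 epochs of 100 steps at batch size 2.
"""

from __future__ import annotations

import numpy as np

from . import pipeline as _pipeline
from . import postprocess as _post
from .metrics import count_r2
from .network import NetworkSpec
from .synthetic import LeafScene, SceneConfig, generate_scene
from .training import GlandSegmentationModel, TrainConfig

__all__ = ["make_level1_scenes", "reduced_level1_study"]

#: per-100x100-tile gland densities of the study scenes (all level 1)
TRAIN_DENSITIES = (14, 20, 26, 32)
VAL_DENSITIES = (16, 30)


def make_level1_scenes(seed: int, densities, scene_height: int = 500,
                       scene_width: int = 500) -> list:
    """One scene per requested density (glands per 100x100-px tile)."""
    rng = np.random.default_rng(seed)
    tiles = (scene_height // 100) * (scene_width // 100)
    scenes = []
    for density in densities:
        cfg = SceneConfig(
            width=scene_width, height=scene_height,
            spot_count=int(density * tiles),
            spot_radius_range=(1, 3),
            vein_count=5,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        scenes.append(generate_scene(cfg))
    return scenes


def reduced_level1_study(seed: int = 0, epochs: int = 5,
                         steps_per_epoch: int = 100, base_channels: int = 8,
                         tau: float = 0.5) -> dict:
    """Run the reduced training + counting study; returns a result dict.

    Keys: ``results`` (the fitted :class:`SegmentationResults`), ``f1``,
    ``miou`` (held-out tile metrics of the retained parameters),
    ``count_r2`` (per-tile counting agreement over the held-out scenes),
    ``pred_counts`` / ``ref_counts``, and ``n_val_tiles``.
    """
    rng = np.random.default_rng(seed)
    train_scenes = make_level1_scenes(
        int(rng.integers(0, 2 ** 31 - 1)), TRAIN_DENSITIES,
        scene_height=500, scene_width=1000)          # 4 x 50 = 200 tiles
    val_scenes = make_level1_scenes(
        int(rng.integers(0, 2 ** 31 - 1)), VAL_DENSITIES,
        scene_height=500, scene_width=500)           # 2 x 25 = 50 tiles

    config = TrainConfig(epochs=epochs, steps_per_epoch=steps_per_epoch,
                         batch_size=2, seed=int(rng.integers(0, 2 ** 31 - 1)),
                         tau=tau)
    spec = NetworkSpec(input_size=120, base_channels=base_channels)
    model = GlandSegmentationModel.from_scenes(train_scenes, val_scenes,
                                               spec=spec, config=config)
    results = model.fit()

    fcfg = _post.FilterConfig(min_area=2, closing_radius=0)
    pred_counts, ref_counts = [], []
    for scene in val_scenes:
        pred_mask = results.predict(scene.image, tau=tau)
        pred_counts.append(_pipeline.per_tile_counts(pred_mask, filter_config=fcfg))
        ref_counts.append(_pipeline.per_tile_counts(scene.mask, filter_config=fcfg))
    pred_counts = np.concatenate(pred_counts)
    ref_counts = np.concatenate(ref_counts)

    final = results.final_metrics
    return {
        "results": results,
        "f1": float(final["val_f1"]),
        "miou": float(final["val_miou"]),
        "count_r2": count_r2(pred_counts, ref_counts),
        "pred_counts": pred_counts,
        "ref_counts": ref_counts,
        "n_val_tiles": len(ref_counts),
    }
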