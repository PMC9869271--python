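"""Synthetic leaf scenes with known gland masks and counts.

Real pigment-gland images are dark, near-circular spots of roughly
100-400 um diameter scattered densely over a green leaf blade, crossed by
darker vein shadows that a segmenter must learn to ignore. At the working
scale of ~45 um/px a gland is about 2-9 px across. The generator emulates
exactly these features on demand: a noisy green background, dark curved
vein strokes (image only, never the mask), and non-overlapping dark disks
whose union is the ground-truth mask — so the true count per scene is known
by construction.

Density levels follow the field convention of glands per 4.5 x 4.5 mm
(100 x 100 px) area: fewer than 40 is level 1, 40-79 level 2, 80 or more
level 3.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk

__all__ = [
    "SceneConfig",
    "LeafScene",
    "PlacementError",
    "generate_scene",
    "assign_density_level",
    "augment_flips",
    "write_scenes",
]

#: side of the reference counting area (px); 100 px = 4.5 mm at 45 um/px
REFERENCE_TILE = 100


class PlacementError(RuntimeError):
    """Raised when non-overlapping spot placement cannot be completed."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    ``spot_radius_range`` (inclusive, px) defaults to (1, 5): at the
    inferred 45 um/px scale the 100-400 um gland diameter range maps to
    about 2-9 px. ``microns_per_px`` is exposed because the calibration is
    inferred, not measured. Intensity fields are 8-bit gray levels.
    """

    width: int = 400
    height: int = 300
    spot_count: int = 60
    spot_radius_range: tuple = (1, 5)
    spot_intensity: tuple = (30, 80)
    background_green: tuple = (130, 170)
    vein_count: int = 4
    vein_width: int = 3
    vein_darkness: int = 45
    noise_sd: float = 6.0
    microns_per_px: float = 45.0
    seed: int = 0

    def __post_init__(self):
        if self.width < 8 or self.height < 8:
            raise ValueError("scene must be at least 8x8 px")
        if self.spot_count < 0:
            raise ValueError("spot_count must be non-negative")
        lo, hi = self.spot_radius_range
        if lo < 1 or hi < lo:
            raise ValueError("spot_radius_range must satisfy 1 <= lo <= hi")


@dataclass
class LeafScene:
    """A scene: RGB image, {0,1} gland mask, and the true gland count."""

    image: np.ndarray          # (H, W, 3) uint8
    mask: np.ndarray           # (H, W) uint8 in {0, 1}
    count: int
    density_level: int
    config: SceneConfig | None = None
    scene_id: str = ""

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask dimensions differ")


def assign_density_level(count: int, area_px: int = REFERENCE_TILE ** 2) -> int:
    """Density level of a gland count over ``area_px`` pixels.

    Counts are normalised to the reference 100x100-px (4.5x4.5 mm) area;
    half-open bins: [0, 40) -> 1, [40, 80) -> 2, [80, inf) -> 3.
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    per_ref = count * (REFERENCE_TILE ** 2) / area_px
    if per_ref < 40:
        return 1
    if per_ref < 80:
        return 2
    return 3


def _draw_vein(image: np.ndarray, rng: np.random.Generator,
               width_px: int, darkness: int) -> None:
    """Darken a random quadratic-curve stroke across the image (image only)."""
    h, w = image.shape[:2]
    # endpoints on opposite borders, control point anywhere
    if rng.random() < 0.5:
        p0 = np.array([rng.uniform(0, h), 0.0])
        p2 = np.array([rng.uniform(0, h), w - 1.0])
    else:
        p0 = np.array([0.0, rng.uniform(0, w)])
        p2 = np.array([h - 1.0, rng.uniform(0, w)])
    p1 = np.array([rng.uniform(0, h), rng.uniform(0, w)])
    t = np.linspace(0, 1, 4 * max(h, w))[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2
    stroke = np.zeros((h, w), dtype=bool)
    r = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
    c = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
    stroke[r, c] = True
    if width_px > 1:
        from scipy.ndimage import binary_dilation
        rad = (width_px - 1) // 2 + 1
        yy, xx = np.mgrid[-rad:rad + 1, -rad:rad + 1]
        stroke = binary_dilation(stroke, yy ** 2 + xx ** 2 <= (width_px / 2) ** 2)
    shade = image[stroke].astype(np.int16) - darkness
    image[stroke] = np.clip(shade, 0, 255).astype(np.uint8)


def generate_scene(config: SceneConfig) -> LeafScene:
    """Render one scene deterministically from ``config.seed``.

    Spots are placed by rejection sampling with enough rim clearance that
    no two rendered disks can share or touch a mask pixel, so the mask's
    8-connected component count always equals ``spot_count``. Raises :class:`PlacementError` (naming
    the achievable maximum) if the requested density does not fit.
    """
    # independent substreams so the mask depends only on spot placement:
    # changing vein or noise settings must never move a spot
    ss = np.random.SeedSequence(config.seed)
    rng_bg, rng, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))
    h, w = config.height, config.width

    # background: green leaf blade with mild texture
    g_lo, g_hi = config.background_green
    base_g = rng_bg.uniform(g_lo, g_hi)
    image = np.empty((h, w, 3), dtype=np.float32)
    image[..., 0] = base_g * 0.62
    image[..., 1] = base_g
    image[..., 2] = base_g * 0.55

    for _ in range(config.vein_count):
        img8 = np.clip(image, 0, 255).astype(np.uint8)
        _draw_vein(img8, rng_bg, config.vein_width, config.vein_darkness)
        image = img8.astype(np.float32)

    # spot placement: centres/radii accepted only with rim clearance > 2 px
    r_lo, r_hi = config.spot_radius_range
    centers = np.empty((0, 2))
    radii = np.empty(0)
    max_attempts = 200 * max(config.spot_count, 1) + 1000
    attempts = 0
    while len(radii) < config.spot_count:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {config.spot_count} non-overlapping spots in "
                f"{w}x{h} px after {max_attempts} attempts; achievable maximum "
                f"here is about {len(radii)}")
        attempts += 1
        r = rng.integers(r_lo, r_hi + 1)
        cy = rng.uniform(r + 1, h - r - 1)
        cx = rng.uniform(r + 1, w - r - 1)
        if len(radii):
            d = np.hypot(centers[:, 0] - cy, centers[:, 1] - cx)
            # drawn disk radii are r+0.5 and 8-adjacent pixel centres sit
            # sqrt(2) apart, so rims must clear by more than 1+sqrt(2) px
            # for the components to stay separate; 2.5 gives margin
            if (d <= radii + r + 2.5).any():
                continue
        centers = np.vstack([centers, (cy, cx)])
        radii = np.append(radii, r)

    mask = np.zeros((h, w), dtype=np.uint8)
    s_lo, s_hi = config.spot_intensity
    for (cy, cx), r in zip(centers, radii):
        rr, cc = _disk((cy, cx), r + 0.5, shape=(h, w))
        mask[rr, cc] = 1
        level = rng.uniform(s_lo, s_hi)
        image[rr, cc, 0] = level * 1.05
        image[rr, cc, 1] = level * 0.85
        image[rr, cc, 2] = level * 0.75

    if config.noise_sd > 0:
        image += rng_noise.normal(0.0, config.noise_sd, size=image.shape)
    image = np.clip(image, 0, 255).astype(np.uint8)

    level = assign_density_level(config.spot_count, area_px=h * w)
    return LeafScene(image=image, mask=mask, count=config.spot_count,
                     density_level=level, config=config)


def augment_flips(scenes: list) -> list:
    """Expand each scene into its four axis-flip variants.

    Returns, per input scene: the original, the horizontal flip, the
    vertical flip, and the 180-degree rotation ("mirrored"), with masks
    transformed identically — 9 scenes in, 36 out.
    """
    if not scenes:
        raise ValueError("augment_flips needs a non-empty scene list")
    variants = [
        ("orig", lambda a: a),
        ("fliph", lambda a: a[:, ::-1].copy()),
        ("flipv", lambda a: a[::-1].copy()),
        ("rot180", lambda a: a[::-1, ::-1].copy()),
    ]
    out = []
    for scene in scenes:
        for tag, op in variants:
            out.append(LeafScene(
                image=op(scene.image), mask=op(scene.mask),
                count=scene.count, density_level=scene.density_level,
                config=scene.config,
                scene_id=f"{scene.scene_id}_{tag}" if scene.scene_id else tag))
    return out


def write_scenes(scenes: list, out_dir, image_format: str = "png") -> pd.DataFrame:
    """Write scene images/masks and return (and save) the manifest table."""
    from . import dataio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, scene in enumerate(scenes):
        stem = scene.scene_id or f"scene_{i:04d}"
        img_path = out_dir / f"{stem}.{image_format}"
        mask_path = out_dir / f"{stem}_mask.png"
        dataio.write_image(img_path, scene.image)
        dataio.write_mask(mask_path, scene.mask)
        rows.append({
            "scene_id": stem,
            "seed": scene.config.seed if scene.config else -1,
            "count": scene.count,
            "density_level": scene.density_level,
            "image_path": str(img_path),
            "mask_path": str(mask_path),
        })
    manifest = pd.DataFrame(rows, columns=["scene_id", "seed", "count",
                                           "density_level", "image_path",
                                           "mask_path"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
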