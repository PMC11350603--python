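"""Synthetic crown scenes with point-annotated shoot blobs.

Emulates the statistical structure of a top-down conifer-crown counting
dataset: many small bright blobs (new shoots) scattered over one of three
procedural background textures (road, soil, grass), with per-image counts in
a configurable range.  At the reference canvas of 1024 x 768 the default
count range is 80-246; smaller canvases scale the range linearly with area so
local shoot density stays realistic, unless an explicit ``count_range`` is
given.

Shoots are rendered as anisotropic Gaussian bumps with random orientation,
brightness and a green-yellow tint — the simplest appearance that still makes
density estimation non-trivial (overlap, border truncation, texture clutter).
Everything is deterministic in (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .annotations_io import (DatasetManifest, ManifestEntry, PointAnnotationSet,
                             write_manifest, write_points)

__all__ = ["SceneSpec", "generate_scene", "generate_dataset",
           "REFERENCE_AREA", "REFERENCE_COUNT_RANGE"]

REFERENCE_AREA = 1024 * 768
REFERENCE_COUNT_RANGE = (80, 246)
BACKGROUND_CLASSES = ("road", "soil", "grass")


@dataclass(frozen=True)
class SceneSpec:
    image_height: int = 768
    image_width: int = 1024
    count_range: tuple | None = None   # None: reference range scaled by area
    blob_sigma_range: tuple = (1.5, 3.0)
    background_class: str = "grass"
    brightness_jitter: float = 0.1
    rng_seed: int = 0

    def __post_init__(self):
        if self.image_height % 8 or self.image_width % 8:
            raise ValueError(
                f"image dims ({self.image_height}, {self.image_width}) must be "
                "divisible by 8 (backbone stride)")
        if self.background_class not in BACKGROUND_CLASSES:
            raise ValueError(f"background_class must be one of {BACKGROUND_CLASSES}")
        lo, hi = self.resolved_count_range
        if lo < 0 or lo > hi:
            raise ValueError(f"invalid count range ({lo}, {hi})")
        if self.blob_sigma_range[0] <= 0 or self.blob_sigma_range[0] > self.blob_sigma_range[1]:
            raise ValueError("blob_sigma_range must be positive and ordered")

    @property
    def resolved_count_range(self) -> tuple:
        """Count range after area scaling (when no explicit range is set)."""
        if self.count_range is not None:
            lo, hi = self.count_range
            return int(lo), int(hi)
        area = self.image_height * self.image_width
        factor = area / REFERENCE_AREA
        lo = max(1, int(round(REFERENCE_COUNT_RANGE[0] * factor)))
        hi = max(lo, int(round(REFERENCE_COUNT_RANGE[1] * factor)))
        return lo, hi


def _background(rng: np.random.Generator, height: int, width: int, kind: str) -> np.ndarray:
    """Procedural background texture on [0, 1], (H, W, 3)."""
    noise = rng.normal(size=(height, width))
    if kind == "road":
        # smooth grey with faint horizontal streaking
        base = np.full((height, width, 3), 0.45)
        streaks = gaussian_filter(noise, sigma=(1.0, 12.0)) * 0.06
        base += streaks[..., None]
    elif kind == "soil":
        # brownish mid-frequency clumps
        tex = gaussian_filter(noise, sigma=3.0) * 0.35
        base = np.stack([0.42 + tex, 0.30 + 0.8 * tex, 0.20 + 0.5 * tex], axis=-1)
    else:  # grass
        # green high-frequency texture
        tex = gaussian_filter(noise, sigma=1.0) * 0.30
        base = np.stack([0.15 + 0.4 * tex, 0.35 + tex, 0.12 + 0.3 * tex], axis=-1)
    return np.clip(base, 0.0, 1.0)


def _render_blob(canvas: np.ndarray, x: float, y: float, sigma_a: float,
                 sigma_b: float, theta: float, amplitude: float, tint: np.ndarray) -> None:
    """Add one anisotropic Gaussian bump (additive brightness, tinted)."""
    height, width = canvas.shape[:2]
    half = int(np.ceil(3.5 * max(sigma_a, sigma_b))) + 1
    r0, r1 = max(0, int(y) - half), min(height, int(y) + half + 1)
    c0, c1 = max(0, int(x) - half), min(width, int(x) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1)[:, None] - y
    cols = np.arange(c0, c1)[None, :] - x
    ct, st = np.cos(theta), np.sin(theta)
    u = cols * ct + rows * st
    v = -cols * st + rows * ct
    bump = amplitude * np.exp(-0.5 * ((u / sigma_a) ** 2 + (v / sigma_b) ** 2))
    canvas[r0:r1, c0:c1] += bump[..., None] * tint


def generate_scene(spec: SceneSpec, seed: int) -> tuple[np.ndarray, PointAnnotationSet]:
    """Render one scene: (H, W, 3) uint8 image + its point annotations.

    Deterministic: identical (spec, seed) produces byte-identical output.
    """
    rng = np.random.default_rng([spec.rng_seed, seed])
    h, w = spec.image_height, spec.image_width
    img = _background(rng, h, w, spec.background_class)

    lo, hi = spec.resolved_count_range
    count = int(rng.integers(lo, hi + 1))
    xs = rng.uniform(0.0, w, size=count)
    ys = rng.uniform(0.0, h, size=count)
    # bright yellow-green shoot tint, slightly varied per blob
    for x, y in zip(xs, ys):
        sigma_a = rng.uniform(*spec.blob_sigma_range)
        sigma_b = sigma_a * rng.uniform(0.55, 1.0)
        theta = rng.uniform(0.0, np.pi)
        amplitude = rng.uniform(0.35, 0.6)
        tint = np.array([0.75, 0.95, 0.35]) + rng.normal(0.0, 0.04, 3)
        _render_blob(img, x, y, sigma_a, sigma_b, theta, amplitude, np.clip(tint, 0, 1))

    if spec.brightness_jitter > 0:
        img *= 1.0 + rng.uniform(-spec.brightness_jitter, spec.brightness_jitter)
    img = np.clip(img, 0.0, 1.0)
    image_u8 = (img * 255.0 + 0.5).astype(np.uint8)
    points = PointAnnotationSet(image_id=f"scene_{seed:05d}",
                                points=np.stack([xs, ys], axis=1))
    return image_u8, points


def generate_dataset(n_images: int, spec: SceneSpec, out_dir, seed: int = 0,
                     ratios=(0.7, 0.2, 0.1)) -> DatasetManifest:
    """Write a full synthetic dataset: PNG images, JSON annotations, CSV manifest.

    Needs at least 3 images (one per split).  Splitting follows the package's
    floor-rule 7:2:1 convention via :func:`shootcount.annotations_io.split_dataset`.
    """
    from .annotations_io import split_dataset  # local import avoids cycle at module load

    if n_images < 3:
        raise ValueError("need at least 3 images (one per split)")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)

    ids = []
    for i in range(n_images):
        image, points = generate_scene(spec, seed=(seed * 100_000 + i) % (2 ** 31))
        image_id = f"scene_{i:05d}"
        Image.fromarray(image).save(out_dir / "images" / f"{image_id}.png")
        write_points(PointAnnotationSet(image_id=image_id, points=points.points),
                     out_dir / "annotations" / f"{image_id}.json")
        ids.append(image_id)

    skeleton = split_dataset(ids, ratios=ratios, seed=seed)
    entries = [ManifestEntry(image_path=f"images/{e.image_path}.png",
                             annotation_path=f"annotations/{e.image_path}.json",
                             split=e.split, labeled=e.labeled)
               for e in skeleton.entries]
    manifest = DatasetManifest(entries=entries, labeled_percentage=1.0, split_seed=seed)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
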