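"""Patch-aligned random masking and training-time augmentation.

Masking hides a fixed fraction of 16x16-aligned patches of an unlabeled image
(masked-image-modeling style): the student must infer the hidden shoots from
context, while the teacher sees the unmasked view.  The number of masked
patches is round(ratio x n_patches) with round-half-up, chosen uniformly
without replacement, and re-drawn every training iteration.

Augmentation is the usual photometric + geometric stack for point-annotated
imagery: brightness jitter (points untouched), horizontal flip, isotropic
rescale and crop (points transformed with the pixels; points leaving the crop
are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .annotations_io import PointAnnotationSet

__all__ = ["MaskSpec", "PatchMask", "AugmentParams", "random_patch_mask",
           "apply_mask", "augment"]


@dataclass(frozen=True)
class MaskSpec:
    patch_size: int = 16
    ratio: float = 0.1
    fill_value: float = 0.5   # dataset mean intensity on the [0, 1] scale
    rng_seed: int = 0

    def __post_init__(self):
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError("ratio must lie in [0, 1]")


@dataclass(frozen=True)
class PatchMask:
    grid: np.ndarray        # (H/patch, W/patch) boolean
    patch_size: int

    @property
    def pixel_mask(self) -> np.ndarray:
        """Nearest-neighbour expansion of the patch grid to pixel resolution."""
        return np.kron(self.grid, np.ones((self.patch_size, self.patch_size), dtype=bool))

    @property
    def masked_patch_count(self) -> int:
        return int(self.grid.sum())


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def random_patch_mask(height: int, width: int, spec: MaskSpec, seed: int) -> PatchMask:
    """Draw a patch mask: round(ratio x n_patches) patches, uniform without
    replacement, deterministic under a fixed seed."""
    p = spec.patch_size
    if height % p or width % p:
        raise ValueError(f"image dims ({height}, {width}) not divisible by patch size {p}")
    gh, gw = height // p, width // p
    n_patches = gh * gw
    n_masked = _round_half_up(spec.ratio * n_patches)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_patches, size=n_masked, replace=False)
    grid = np.zeros(n_patches, dtype=bool)
    grid[chosen] = True
    return PatchMask(grid=grid.reshape(gh, gw), patch_size=p)


def apply_mask(image: np.ndarray, mask: PatchMask, fill_value: float) -> np.ndarray:
    """Replace masked pixels with ``fill_value`` in every channel; all other
    pixels are returned bit-for-bit unchanged."""
    image = np.asarray(image)
    pm = mask.pixel_mask
    if image.shape[:2] != pm.shape:
        raise ValueError(f"mask shape {pm.shape} does not match image {image.shape[:2]}")
    out = image.copy()
    out[pm] = fill_value
    return out


@dataclass(frozen=True)
class AugmentParams:
    brightness: float = 1.0
    flip: bool = False
    scale: float = 1.0
    crop_origin: tuple = (0, 0)   # (row, col) in the scaled image
    crop_size: tuple | None = None  # (height, width); None = no crop

    @staticmethod
    def sample(rng: np.random.Generator, image_shape, crop_size: int | None,
               brightness_jitter: float = 0.2, flip_prob: float = 0.5,
               scale_range=(0.8, 1.2)) -> "AugmentParams":
        """Draw one random parameter set the way the training loop does."""
        h, w = image_shape[:2]
        scale = float(rng.uniform(*scale_range))
        if crop_size is not None:
            # keep the crop inside the scaled canvas
            scale = max(scale, crop_size / min(h, w) + 1e-9)
        sh, sw = int(round(h * scale)), int(round(w * scale))
        if crop_size is None:
            origin, size = (0, 0), None
        else:
            origin = (int(rng.integers(0, sh - crop_size + 1)),
                      int(rng.integers(0, sw - crop_size + 1)))
            size = (crop_size, crop_size)
        return AugmentParams(
            brightness=float(1.0 + rng.uniform(-brightness_jitter, brightness_jitter)),
            flip=bool(rng.random() < flip_prob),
            scale=scale, crop_origin=origin, crop_size=size)


def augment(image: np.ndarray, points: PointAnnotationSet | None,
            params: AugmentParams) -> tuple[np.ndarray, PointAnnotationSet | None]:
    """Apply brightness/flip/scale/crop to an image and its points.

    Images are float arrays on [0, 1].  Points follow the pixel transform:
    flip maps x -> W - 1 - x, scaling multiplies coordinates, cropping
    subtracts the origin and drops points outside the crop window.
    """
    img = np.asarray(image, dtype=np.float64)
    pts = None if points is None else points.points.copy()

    if params.brightness != 1.0:
        img = np.clip(img * params.brightness, 0.0, 1.0)

    if params.flip:
        img = img[:, ::-1].copy()
        if pts is not None and len(pts):
            pts[:, 0] = img.shape[1] - 1 - pts[:, 0]

    if params.scale != 1.0:
        h, w = img.shape[:2]
        sh, sw = int(round(h * params.scale)), int(round(w * params.scale))
        img = resize(img, (sh, sw) + img.shape[2:], order=1, mode="reflect",
                     anti_aliasing=params.scale < 1.0, preserve_range=True)
        if pts is not None and len(pts):
            pts = pts * params.scale

    if params.crop_size is not None:
        ch, cw = params.crop_size
        r0, c0 = params.crop_origin
        if r0 < 0 or c0 < 0 or r0 + ch > img.shape[0] or c0 + cw > img.shape[1]:
            raise ValueError(
                f"crop {params.crop_size}@{params.crop_origin} exceeds image {img.shape[:2]}")
        img = img[r0:r0 + ch, c0:c0 + cw].copy()
        if pts is not None and len(pts):
            pts = pts - np.array([c0, r0], dtype=np.float64)
            inside = ((pts[:, 0] >= 0) & (pts[:, 0] < cw)
                      & (pts[:, 1] >= 0) & (pts[:, 1] < ch))
            pts = pts[inside]

    out_points = None
    if points is not None:
        out_points = PointAnnotationSet(image_id=points.image_id,
                                        points=pts if pts is not None else np.zeros((0, 2)))
    return img, out_points
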