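"""Ground-truth density maps from point annotations.

Each annotated shoot is spread into a unit-mass 2-D Gaussian whose bandwidth
adapts to local crowding (the geometric adaptive kernel): sigma_i = beta times
the mean distance from point i to its k nearest annotated neighbours.  Kernels
are evaluated on a +/- 4 sigma window and renormalised to unit mass inside the
canvas, so shoots near the border still count as exactly one object and the
map's sum stays equal to the point count.

Also here: the binary segmentation mask that separates dense from empty
regions, sum-preserving block downsampling to the head's 1/8 resolution, and
the per-image density-class labels used by the classification head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .annotations_io import PointAnnotationSet

__all__ = [
    "DensityMap", "DensityClassLabel",
    "geometric_adaptive_density", "adaptive_sigmas", "segmentation_mask",
    "downsample_sum_preserving", "density_class_label", "quantile_bin_edges",
]

#: bandwidth fallback (pixels) when an image has fewer than 2 points and no
#: neighbour distance exists
SINGLE_POINT_SIGMA = 4.0
#: kernel support half-width in units of sigma
TRUNCATION_SIGMAS = 4.0


@dataclass(frozen=True)
class DensityMap:
    """Nonnegative grid whose sum equals the object count.

    ``scale`` is the downsampling factor relative to the source image:
    1 at full resolution, 8 at the regression head's output resolution.
    """

    values: np.ndarray
    scale: int = 1

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("density map must be 2-D")
        if not np.isfinite(v).all():
            raise ValueError("density map has non-finite values")
        if (v < 0).any():
            raise ValueError("density map has negative values")
        object.__setattr__(self, "values", v)

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class DensityClassLabel:
    class_index: int
    bin_edges: tuple


def adaptive_sigmas(points: np.ndarray, k: int = 3, beta: float = 0.3) -> np.ndarray:
    """Per-point Gaussian bandwidths: beta x mean distance to k nearest neighbours.

    With fewer than 2 points there is no neighbour distance; a fixed
    ``SINGLE_POINT_SIGMA`` is used instead.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if beta <= 0:
        raise ValueError("beta must be positive")
    points = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    n = len(points)
    if n < 2:
        return np.full(n, SINGLE_POINT_SIGMA)
    kk = min(k, n - 1)
    tree = cKDTree(points)
    # first neighbour is the point itself
    dists, _ = tree.query(points, k=kk + 1)
    return beta * dists[:, 1:].mean(axis=1)


def geometric_adaptive_density(annotations: PointAnnotationSet, height: int, width: int,
                               k: int = 3, beta: float = 0.3) -> DensityMap:
    """Render the geometric-adaptive-kernel density map for one image."""
    if height < 1 or width < 1:
        raise ValueError("canvas must be at least 1x1")
    points = annotations.points
    annotations.validate_bounds(height, width)
    out = np.zeros((height, width), dtype=np.float64)
    if len(points) == 0:
        return DensityMap(out, scale=1)
    sigmas = adaptive_sigmas(points, k=k, beta=beta)
    for (x, y), sigma in zip(points, sigmas):
        _add_kernel(out, x, y, sigma)
    return DensityMap(out, scale=1)


def _add_kernel(canvas: np.ndarray, x: float, y: float, sigma: float) -> None:
    """Accumulate one unit-mass Gaussian, truncated at +/-4 sigma and
    renormalised over its in-canvas support."""
    height, width = canvas.shape
    half = max(1.0, TRUNCATION_SIGMAS * sigma)
    r0 = max(0, int(np.floor(y - half)))
    r1 = min(height, int(np.ceil(y + half)) + 1)
    c0 = max(0, int(np.floor(x - half)))
    c1 = min(width, int(np.ceil(x + half)) + 1)
    rows = np.arange(r0, r1, dtype=np.float64)
    cols = np.arange(c0, c1, dtype=np.float64)
    gy = np.exp(-((rows - y) ** 2) / (2.0 * sigma ** 2))
    gx = np.exp(-((cols - x) ** 2) / (2.0 * sigma ** 2))
    patch = np.outer(gy, gx)
    mass = patch.sum()
    if mass <= 0:
        # pathologically tiny sigma: all mass on the nearest pixel
        canvas[min(int(round(y)), height - 1), min(int(round(x)), width - 1)] += 1.0
        return
    canvas[r0:r1, c0:c1] += patch / mass


def segmentation_mask(density: DensityMap | np.ndarray, epsilon: float = 1e-3) -> np.ndarray:
    """Binary mask separating dense areas (density > epsilon) from background."""
    values = density.values if isinstance(density, DensityMap) else np.asarray(density)
    return (values > epsilon).astype(np.float64)


def downsample_sum_preserving(density: DensityMap, factor: int) -> DensityMap:
    """Block-sum downsampling: each output cell is the sum of its
    factor x factor block, so the total count is preserved exactly."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    h, w = density.values.shape
    if h % factor or w % factor:
        raise ValueError(f"dimensions ({h}, {w}) not divisible by factor {factor}")
    blocked = density.values.reshape(h // factor, factor, w // factor, factor)
    return DensityMap(blocked.sum(axis=(1, 3)), scale=density.scale * factor)


def density_class_label(count: float, bin_edges) -> DensityClassLabel:
    """Right-open count binning: class = index of the first edge exceeding
    ``count``; counts at or above the last edge land in the last class."""
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.ndim != 1 or len(edges) < 1:
        raise ValueError("bin_edges must be a non-empty 1-D sequence")
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin_edges must be strictly increasing")
    if not np.isfinite(count):
        raise ValueError("count must be finite")
    idx = int(np.searchsorted(edges, count, side="right"))
    idx = min(idx, len(edges) - 1)
    return DensityClassLabel(class_index=idx, bin_edges=tuple(edges.tolist()))


def quantile_bin_edges(counts, n_classes: int = 5) -> np.ndarray:
    """Per-dataset bin edges at the quantiles of labeled-train counts.

    Returns ``n_classes`` edges at quantiles 1/C, 2/C, ..., 1; ties are broken
    by nudging duplicate edges upward so the edges stay strictly increasing.
    """
    counts = np.asarray(list(counts), dtype=np.float64)
    if len(counts) == 0:
        raise ValueError("need at least one count to place bin edges")
    qs = np.arange(1, n_classes + 1) / n_classes
    edges = np.quantile(counts, qs)
    for i in range(1, len(edges)):
        if edges[i] <= edges[i - 1]:
            edges[i] = edges[i - 1] + 1e-6
    return edges
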