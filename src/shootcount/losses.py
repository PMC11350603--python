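"""The full training loss stack.

Labeled branch
    L_RL = SL + lambda1 * L_TV        (regression)
    L_CL = cross-entropy over density classes
where SL is a K-level average-pool pyramid of (1 - SSIM) computed on density
maps Hadamard-masked by the binary segmentation map (density > epsilon), and
L_TV is the count-weighted L1 distance between the *normalised* predicted and
ground-truth maps (so it penalises where mass sits, not how much there is).

Unlabeled branch (mean-teacher consistency)
    L_RU = smooth-L1 between student and teacher density maps, restricted to
           the masked-patch footprint (teacher detached)
    L_CU = smooth-L1 between student and teacher class distributions

Totals: L_L = L_RL + L_CL, L_U = L_RU + L_CU, L = L_L + L_U.

Defaults follow the method's stated constants: epsilon = 1e-3, lambda1 = 0.01,
SSIM stabilisers Z1 = 0.01 / Z2 = 0.03, pyramid depth K = 3.  All terms are
differentiable through the autograd engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import gaussian as gaussian_window

from .augmentation_masking import PatchMask
from .autograd import Tensor, as_tensor, avg_pool2d, conv2d
from .network import ModelOutput

__all__ = [
    "SSIMParams", "LossBreakdown", "ssim_score", "structural_loss", "tv_loss",
    "labeled_regression_loss", "classification_cross_entropy", "smooth_l1",
    "unsupervised_losses", "total_loss",
]

PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class SSIMParams:
    z1: float = 0.01
    z2: float = 0.03
    window: int = 11          # Gaussian local-statistics window (sigma 1.5)
    window_sigma: float = 1.5
    k_levels: int = 3

    def __post_init__(self):
        if self.z1 <= 0 or self.z2 <= 0:
            raise ValueError("stabilisers must be positive")
        if self.k_levels < 1:
            raise ValueError("k_levels must be >= 1")


@dataclass
class LossBreakdown:
    l_rl: float
    l_cl: float
    l_ru: float
    l_cu: float

    @property
    def l_l(self) -> float:
        return self.l_rl + self.l_cl

    @property
    def l_u(self) -> float:
        return self.l_ru + self.l_cu

    @property
    def total(self) -> float:
        return self.l_l + self.l_u


def _as_batch(x) -> Tensor:
    """Promote (H, W) or (N, 1, H, W) input to a 4-D Tensor."""
    t = as_tensor(x)
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    if t.ndim != 4:
        raise ValueError(f"expected 2-D or 4-D input, got shape {t.shape}")
    return t


def _ssim_kernel(h: int, w: int, params: SSIMParams) -> Tensor:
    size = min(params.window, h, w)
    if size % 2 == 0:
        size -= 1
    size = max(size, 1)
    g = gaussian_window(size, std=params.window_sigma)
    k = np.outer(g, g)
    return Tensor((k / k.sum())[None, None])


def ssim_score(x, y, params: SSIMParams = SSIMParams()) -> Tensor:
    """Mean local structural similarity between two grids (scalar Tensor).

    Local means/variances/covariance come from a Gaussian-weighted window
    (valid positions only); the window shrinks to fit grids smaller than 11
    pixels per side.
    """
    x, y = _as_batch(x), _as_batch(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    kern = _ssim_kernel(x.shape[2], x.shape[3], params)
    mu_x = conv2d(x, kern)
    mu_y = conv2d(y, kern)
    var_x = conv2d(x * x, kern) - mu_x * mu_x
    var_y = conv2d(y * y, kern) - mu_y * mu_y
    cov = conv2d(x * y, kern) - mu_x * mu_y
    num = (2.0 * mu_x * mu_y + params.z1) * (2.0 * cov + params.z2)
    den = (mu_x * mu_x + mu_y * mu_y + params.z1) * (var_x + var_y + params.z2)
    return (num / den).mean()


def structural_loss(dm_pred, dm_gt, mask, params: SSIMParams = SSIMParams()) -> Tensor:
    """K-level pyramid structural loss on segmentation-masked density maps.

    SL = (1/K) sum_j [1 - SSIM(Pool_j(pred (.) mask), Pool_j(gt (.) mask))],
    Pool_j average-pooling by 2^(j-1).
    """
    pred, gt = _as_batch(dm_pred), _as_batch(dm_gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    m = np.asarray(mask.values if hasattr(mask, "values") else mask, dtype=np.float64)
    if m.ndim == 2:
        m = m[None, None]
    h, w = pred.shape[2], pred.shape[3]
    k = params.k_levels
    if h % (2 ** (k - 1)) or w % (2 ** (k - 1)) or min(h, w) < 2 ** (k - 1):
        raise ValueError(f"grid ({h}, {w}) cannot support a {k}-level pyramid")
    a, b = pred * Tensor(m), gt * Tensor(m)
    level_losses = []
    for j in range(k):
        if j > 0:
            a, b = avg_pool2d(a, 2), avg_pool2d(b, 2)
        level_losses.append(1.0 - ssim_score(a, b, params))
    total = level_losses[0]
    for term in level_losses[1:]:
        total = total + term
    return total * (1.0 / k)


def tv_loss(d_pred, d_gt) -> Tensor:
    """Count-weighted L1 distance between normalised density maps.

    0.5 * count(gt) * || gt/||gt||_1 - pred/||pred||_1 ||_1 per image, meaned
    over the batch.  Invariant to positive rescaling of the prediction; both
    maps identically zero is defined as loss 0.
    """
    pred, gt = _as_batch(d_pred), _as_batch(d_gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if (pred.data < 0).any() or (gt.data < 0).any():
        raise ValueError("density maps must be nonnegative")
    gt_sum = gt.sum(axis=(1, 2, 3), keepdims=True)
    pred_sum = pred.sum(axis=(1, 2, 3), keepdims=True)
    gt_n = gt / (gt_sum + PROB_FLOOR)
    pred_n = pred / (pred_sum + PROB_FLOOR)
    per_image = 0.5 * Tensor(gt_sum.data.reshape(-1)) * (gt_n - pred_n).abs().sum(axis=(1, 2, 3))
    return per_image.mean()


def labeled_regression_loss(d_pred, d_gt, epsilon: float = 1e-3,
                            lambda1: float = 0.01,
                            params: SSIMParams = SSIMParams()) -> Tensor:
    """L_RL = SL + lambda1 * L_TV, with the segmentation mask taken from the
    ground-truth map at threshold epsilon."""
    gt = _as_batch(d_gt)
    mask = (gt.data > epsilon).astype(np.float64)
    return structural_loss(d_pred, d_gt, mask, params) + lambda1 * tv_loss(d_pred, d_gt)


def classification_cross_entropy(y_gt, y_probs) -> Tensor:
    """Mean -log p[true class] over the labeled batch.

    ``y_gt``: integer class indices, shape (N,).  ``y_probs``: (N, C) rows
    summing to 1.  Probabilities are floored at 1e-12 before the log.
    """
    probs = as_tensor(y_probs)
    if probs.ndim == 1:
        probs = probs.reshape(1, -1)
    y = np.atleast_1d(np.asarray(y_gt, dtype=np.int64))
    n, c = probs.shape
    if len(y) != n:
        raise ValueError("batch size mismatch between labels and probabilities")
    if (y < 0).any() or (y >= c).any():
        raise ValueError("class index out of range")
    row_sums = probs.data.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    onehot = np.zeros((n, c))
    onehot[np.arange(n), y] = 1.0
    logp = probs.clip(lo=PROB_FLOOR).log()
    return -(Tensor(onehot) * logp).sum(axis=1).mean()


def smooth_l1(a, b, beta: float = 1.0) -> Tensor:
    """Huber-style smooth L1, averaged over elements:
    0.5 d^2 / beta for |d| < beta, |d| - 0.5 beta otherwise."""
    a, b = as_tensor(a), as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    d = a - b
    quad_mask = (np.abs(d.data) < beta).astype(np.float64)
    quad = 0.5 * d * d * (1.0 / beta)
    lin = d.abs() - 0.5 * beta
    return (Tensor(quad_mask) * quad + Tensor(1.0 - quad_mask) * lin).mean()


def _footprint_at_scale(mask: PatchMask, scale: int) -> np.ndarray:
    """Downsample the pixel mask to the density-grid resolution: a cell is in
    the footprint if any of its scale x scale pixels is masked."""
    pm = mask.pixel_mask
    h, w = pm.shape
    if h % scale or w % scale:
        raise ValueError(f"mask dims ({h}, {w}) not divisible by scale {scale}")
    return pm.reshape(h // scale, scale, w // scale, scale).max(axis=(1, 3)).astype(np.float64)


def unsupervised_losses(student_out: ModelOutput, teacher_out: ModelOutput,
                        masks: list[PatchMask] | PatchMask, scale: int = 8,
                        beta: float = 1.0) -> tuple[Tensor, Tensor]:
    """(L_RU, L_CU): consistency between student and detached teacher.

    L_RU compares the density maps only inside the masked-patch footprint
    (mask block-reduced to the head's 1/8 grid): per image it is the *sum over
    masked patches* of the patch-averaged smooth-L1, then a mean over the
    batch — so images with more masked patches contribute proportionally more
    consistency signal.  L_CU compares the per-image class probability
    distributions once (the distributions carry no patch index).  The teacher
    is treated as a constant target.
    """
    s_density = student_out.density
    t_density = teacher_out.density.detach()
    n = s_density.shape[0]
    if isinstance(masks, PatchMask):
        masks = [masks] * n
    if len(masks) != n:
        raise ValueError("one patch mask per image required")
    foot = np.stack([_footprint_at_scale(m, scale) for m in masks])[:, None]
    if foot.sum() == 0:
        raise ValueError("empty mask footprint: no masked patches to supervise on")
    # patch-averaged smooth-L1 summed over masked patches = footprint sum
    # divided by the per-patch cell count (patches are disjoint)
    cells_per_patch = max(1, (masks[0].patch_size // scale)) ** 2
    d = s_density - t_density
    quad_mask = (np.abs(d.data) < beta).astype(np.float64)
    elementwise = (Tensor(quad_mask) * (0.5 / beta) * d * d
                   + Tensor(1.0 - quad_mask) * (d.abs() - 0.5 * beta))
    per_image = (elementwise * Tensor(foot)).sum(axis=(1, 2, 3)) / float(cells_per_patch)
    l_ru = per_image.mean()
    l_cu = smooth_l1(student_out.class_probs, teacher_out.class_probs.detach(), beta=beta)
    return l_ru, l_cu


def total_loss(l_rl, l_cl, l_ru, l_cu) -> LossBreakdown:
    """Assemble the breakdown; any non-finite component aborts training."""
    parts = {"l_rl": l_rl, "l_cl": l_cl, "l_ru": l_ru, "l_cu": l_cu}
    values = {}
    for name, part in parts.items():
        v = part.item() if isinstance(part, Tensor) else float(part)
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite loss component {name} = {v}")
        values[name] = v
    return LossBreakdown(**values)
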