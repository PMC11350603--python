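"""The counting network: multiscale backbone, attention feature fusion, and
multiscale-dilated regression/classification heads.

Architecture
------------
*Backbone.*  A VGG19-style convolutional stack modified so its last three
stages all sit at 1/8 input resolution: pooling is kept after stages 1-3 and
removed afterwards, with stages 4-5 using dilation-2 convolutions to preserve
their receptive field.  Stage outputs f3/f4/f5 carry 256/512/512 channels at
full width (scaled by ``width_mult`` in the thin desk profile).

*Fusion.*  Attention feature fusion (AFF) blends a low-level map L and a
high-level map H through a gate M produced by a multiscale channel attention
module (MS-CAM) evaluated on L + H:

    W = M (.) L + (1 - M) (.) H,   M = sigmoid(G(F) + L_loc(F)) in (0, 1)

where L_loc is a pointwise-conv bottleneck applied per location and G is the
same bottleneck applied to the global-average-pooled vector, broadcast back
over space.  Fusion order: AFF(f4, f5) -> 1x1 projection to 256 channels ->
AFF(f3, .).

*Heads.*  A multiscale dilated convolution (MDC) block — three parallel 3x3
columns with dilations 1/2/3 (the smallest hole-free set), concatenated, 1x1
projected and added to an identity shortcut — feeds a regression head
(3x3 + 1x1 convs, ReLU output so the density map is nonnegative) and a
classification head (two 1x1 convs, global average pooling, softmax over C
density classes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autograd import Tensor, concatenate

__all__ = ["NetworkConfig", "FeatureMaps", "ModelOutput", "Backbone",
           "MSCam", "AFF", "MDCBlock", "ShootCountNet"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture knobs.  ``width_mult=1`` is the full profile
    (256/512/512-channel stage outputs); the desk-scale profile thins every
    stage by the same factor."""

    width_mult: float = 1.0
    stage_depths: tuple = (2, 2, 4, 4, 4)     # convs per VGG19 stage
    n_classes: int = 5
    mscam_reduction: int = 4
    mdc_dilations: tuple = (1, 2, 3)
    init_seed: int = 0

    def stage_channels(self) -> list:
        base = (64, 128, 256, 512, 512)
        return [max(2, int(round(c * self.width_mult))) for c in base]


@dataclass
class FeatureMaps:
    """The three 1/8-resolution stage outputs fed to fusion."""
    f3: Tensor
    f4: Tensor
    f5: Tensor


@dataclass
class ModelOutput:
    density: Tensor       # (N, 1, H/8, W/8), nonnegative
    class_logits: Tensor  # (N, C)
    class_probs: Tensor   # (N, C), rows sum to 1

    def detach(self) -> "ModelOutput":
        return ModelOutput(density=self.density.detach(),
                           class_logits=self.class_logits.detach(),
                           class_probs=self.class_probs.detach())


class Backbone(nn.Module):
    """VGG-style extractor with stages 3-5 held at 1/8 resolution."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        chans = cfg.stage_channels()
        self.stages = []
        in_ch = 3
        for stage_idx, (out_ch, depth) in enumerate(zip(chans, cfg.stage_depths)):
            dilation = 2 if stage_idx >= 3 else 1
            convs = []
            for _ in range(depth):
                convs.append(nn.Conv2d(in_ch, out_ch, 3, padding=dilation,
                                       dilation=dilation, rng=rng))
                in_ch = out_ch
            self.stages.append(convs)

    def forward(self, x: Tensor) -> FeatureMaps:
        n, c, h, w = x.shape
        if h % 8 or w % 8:
            raise ValueError(f"input dims ({h}, {w}) must be divisible by 8")
        feats = {}
        for stage_idx, convs in enumerate(self.stages):
            for conv in convs:
                x = nn.relu(conv(x))
            if stage_idx >= 2:
                feats[stage_idx] = x
            if stage_idx < 3:          # pool after stages 1-3 only
                x = nn.maxpool2(x)
                if stage_idx == 2:
                    feats[2] = x       # f3 is the pooled stage-3 output (1/8 res)
        return FeatureMaps(f3=feats[2], f4=feats[3], f5=feats[4])


class MSCam(nn.Module):
    """Multiscale channel attention: local pointwise-conv branch plus a
    global-average-pooling branch through the same bottleneck shape."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        mid = max(1, channels // reduction)
        self.local_down = nn.Conv2d(channels, mid, 1, rng=rng)
        self.local_up = nn.Conv2d(mid, channels, 1, rng=rng)
        self.global_down = nn.Conv2d(channels, mid, 1, rng=rng)
        self.global_up = nn.Conv2d(mid, channels, 1, rng=rng)

    def gate(self, f: Tensor) -> Tensor:
        local = self.local_up(nn.relu(self.local_down(f)))
        pooled = nn.global_avg_pool(f)
        glob = self.global_up(nn.relu(self.global_down(pooled)))
        return nn.sigmoid(local + glob)   # broadcasts glob over space

    def forward(self, f: Tensor) -> Tensor:
        return f * self.gate(f)


class AFF(nn.Module):
    """Attention feature fusion of a low-level and a high-level map."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        self.mscam = MSCam(channels, reduction, rng)

    def forward(self, low: Tensor, high: Tensor) -> Tensor:
        if low.shape != high.shape:
            raise ValueError(f"AFF inputs must match: {low.shape} vs {high.shape}")
        m = self.mscam.gate(low + high)
        return m * low + (1.0 - m) * high


class MDCBlock(nn.Module):
    """Three parallel dilated 3x3 columns + 1x1 projection + shortcut."""

    def __init__(self, channels: int, dilations: tuple, rng: np.random.Generator):
        self.columns = [nn.Conv2d(channels, channels, 3, padding=d, dilation=d, rng=rng)
                        for d in dilations]
        self.project = nn.Conv2d(channels * len(dilations), channels, 1, rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        cols = [nn.relu(col(f)) for col in self.columns]
        merged = self.project(concatenate(cols, axis=1))
        return merged + f


class ShootCountNet(nn.Module):
    """Full forward model: density map at 1/8 resolution + density-class
    probability distribution."""

    def __init__(self, cfg: NetworkConfig | None = None):
        self.cfg = cfg or NetworkConfig()
        rng = np.random.default_rng(self.cfg.init_seed)
        chans = self.cfg.stage_channels()
        c3, c5 = chans[2], chans[4]
        self.backbone = Backbone(self.cfg, rng)
        self.aff_high = AFF(c5, self.cfg.mscam_reduction, rng)       # f4 (+) f5
        self.reduce = nn.Conv2d(c5, c3, 1, rng=rng)                  # 512 -> 256
        self.aff_low = AFF(c3, self.cfg.mscam_reduction, rng)        # f3 (+) reduced
        self.mdc = MDCBlock(c3, self.cfg.mdc_dilations, rng)
        mid = max(2, c3 // 2)
        self.reg_conv = nn.Conv2d(c3, mid, 3, padding=1, rng=rng)
        self.reg_out = nn.Conv2d(mid, 1, 1, rng=rng)
        self.cls_conv = nn.Conv2d(c3, mid, 1, rng=rng)
        self.cls_out = nn.Conv2d(mid, self.cfg.n_classes, 1, rng=rng)

    def forward(self, image: Tensor) -> ModelOutput:
        feats = self.backbone(image)
        fused_high = self.aff_high(feats.f4, feats.f5)
        fused_high = self.reduce(fused_high)
        fused = self.aff_low(feats.f3, fused_high)
        fused = self.mdc(fused)
        density = nn.relu(self.reg_out(nn.relu(self.reg_conv(fused))))
        cls = self.cls_out(nn.relu(self.cls_conv(fused)))
        logits = nn.global_avg_pool(cls).reshape(cls.shape[0], self.cfg.n_classes)
        probs = nn.softmax(logits, axis=1)
        return ModelOutput(density=density, class_logits=logits, class_probs=probs)


def images_to_tensor(images: np.ndarray) -> Tensor:
    """(N, H, W, 3) floats on [0,1] -> (N, 3, H, W) Tensor."""
    arr = np.asarray(images, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[None]
    return Tensor(arr.transpose(0, 3, 1, 2))
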