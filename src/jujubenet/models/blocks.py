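"""Residual blocks and attention modules.

``ConvNeXtBlock`` is the standard inverted-bottleneck residual block:
depthwise 7x7 -> LayerNorm -> pointwise MLP (4x expansion, GELU) -> layer
scale -> drop path -> residual add.

``MDCBlock`` is the lightweight two-branch variant: the input is split into
two half-width channel groups; one half runs through a ConvNeXt-style branch,
the other through a wide-residual branch of two consecutive depthwise
convolutions; the branch outputs are concatenated, drop-pathed and added back
to the input.

``CBAM`` applies sequential channel attention (shared-MLP over spatial avg-
and max-pooled descriptors, sigmoid gate ``M_c``) and spatial attention
(k x k convolution over channel-wise mean/max maps, sigmoid gate ``M_s``):

    F'  = M_c(F) (x) F
    F'' = M_s(F') (x) F'
"""

from __future__ import annotations

import numpy as np

from ..nn import (
    Conv2d,
    DropPath,
    GELU,
    LayerNorm,
    Linear,
    Module,
    Parameter,
    Sequential,
    Tensor,
)
from .config import CBAMConfig, MDCVariant

__all__ = ["ConvNeXtBlock", "MDCBlock", "ChannelAttention", "SpatialAttention", "CBAM",
           "drop_path"]


def drop_path(x: Tensor, rate: float, training: bool, rng: np.random.Generator) -> Tensor:
    """Functional stochastic depth (see :class:`jujubenet.nn.DropPath`)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"drop-path rate must lie in [0, 1), got {rate}")
    x = Tensor.as_tensor(x)
    if not training or rate == 0.0:
        return x
    keep = 1.0 - rate
    shape = (x.shape[0],) + (1,) * (x.ndim - 1)
    mask = (rng.random(shape) < keep).astype(np.float32) / keep
    return x * Tensor(mask)


def _scale_channels(x: Tensor, gamma: Parameter) -> Tensor:
    return x * gamma.reshape(1, -1, 1, 1)


class ConvNeXtBlock(Module):
    def __init__(self, dim: int, drop_path: float = 0.0, layer_scale_init: float = 1e-6,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.dim = dim
        self.dwconv = Conv2d(dim, dim, 7, padding=3, groups=dim, rng=rng)
        self.norm = LayerNorm(dim)
        self.pwconv1 = Linear(dim, 4 * dim, rng=rng)
        self.act = GELU()
        self.pwconv2 = Linear(4 * dim, dim, rng=rng)
        self.gamma = Parameter(np.full(dim, layer_scale_init, dtype=np.float32))
        self.drop_path = DropPath(drop_path)

    def forward(self, x: Tensor) -> Tensor:
        y = self.dwconv(x)
        y = y.transpose(0, 2, 3, 1)          # NCHW -> NHWC for norm + MLP
        y = self.norm(y)
        y = self.pwconv2(self.act(self.pwconv1(y)))
        y = y * self.gamma
        y = y.transpose(0, 3, 1, 2)
        return x + self.drop_path(y)

    def out_shape(self, s):
        return tuple(s)

    def macs(self, s):
        c, h, w = s
        return h * w * (49 * c + 4 * c * c + 4 * c * c)


class MDCBlock(Module):
    """Two-branch residual block at half width per branch."""

    def __init__(self, dim: int, variant: MDCVariant, drop_path: float = 0.0,
                 layer_scale_init: float = 1e-6, rng: np.random.Generator | None = None):
        super().__init__()
        if dim % 2:
            raise ValueError(f"MDC block needs an even channel count, got {dim}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.dim = dim
        self.variant = variant
        c = dim // 2
        self.half = c
        e, k = variant.branch_a_expansion, variant.branch_b_kernel
        # branch A: ConvNeXt design at half width
        self.a_dwconv = Conv2d(c, c, 7, padding=3, groups=c, rng=rng)
        self.a_norm = LayerNorm(c)
        self.a_pwconv1 = Linear(c, e * c, rng=rng)
        self.a_act = GELU()
        self.a_pwconv2 = Linear(e * c, c, rng=rng)
        self.a_gamma = Parameter(np.full(c, layer_scale_init, dtype=np.float32))
        # branch B: wide-residual pair of depthwise convolutions
        self.b_norm = LayerNorm(c, data_format="channels_first")
        self.b_dw1 = Conv2d(c, c, k, padding=k // 2, groups=c, rng=rng)
        self.b_dw2 = Conv2d(c, c, k, padding=k // 2, groups=c, rng=rng)
        self.b_act = GELU()
        if variant.branch_b_pointwise == "per_conv":
            self.b_pw1 = Conv2d(c, c, 1, rng=rng)
            self.b_pw2 = Conv2d(c, c, 1, rng=rng)
        elif variant.branch_b_pointwise == "single_final":
            self.b_pw2 = Conv2d(c, c, 1, rng=rng)
        self.b_gamma = Parameter(np.full(c, layer_scale_init, dtype=np.float32))
        self.drop_path = DropPath(drop_path)

    def forward(self, x: Tensor) -> Tensor:
        c = self.half
        xa = x.narrow(1, 0, c)
        xb = x.narrow(1, c, c)
        # branch A
        ya = self.a_dwconv(xa).transpose(0, 2, 3, 1)
        ya = self.a_norm(ya)
        ya = self.a_pwconv2(self.a_act(self.a_pwconv1(ya)))
        ya = (ya * self.a_gamma).transpose(0, 3, 1, 2)
        # branch B
        yb = self.b_norm(xb)
        yb = self.b_act(self.b_dw1(yb))
        if hasattr(self, "b_pw1"):
            yb = self.b_pw1(yb)
        yb = self.b_act(self.b_dw2(yb))
        if hasattr(self, "b_pw2"):
            yb = self.b_pw2(yb)
        yb = _scale_channels(yb, self.b_gamma)
        y = Tensor.concat([ya, yb], axis=1)
        return x + self.drop_path(y)

    def out_shape(self, s):
        return tuple(s)

    def macs(self, s):
        _, h, w = s
        c = self.half
        e, k = self.variant.branch_a_expansion, self.variant.branch_b_kernel
        total = 49 * c + 2 * e * c * c          # branch A dwconv + MLP
        total += 2 * k * k * c                  # branch B depthwise pair
        if self.variant.branch_b_pointwise == "per_conv":
            total += 2 * c * c
        elif self.variant.branch_b_pointwise == "single_final":
            total += c * c
        return total * h * w


class ChannelAttention(Module):
    """Sigmoid channel gate from spatially pooled descriptors.

    ``M_c(F) = sigmoid(MLP(avgpool(F)) + MLP(maxpool(F)))`` with a shared
    two-layer bottleneck C -> C/r -> C (ReLU in between).
    """

    def __init__(self, channels: int, cfg: CBAMConfig, rng: np.random.Generator | None = None):
        super().__init__()
        r = cfg.reduction_ratio
        if channels % r:
            raise ValueError(f"reduction ratio {r} must divide channel count {channels}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.fc1 = Linear(channels, channels // r, rng=rng)
        self.fc2 = Linear(channels // r, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=(2, 3))                     # (B, C)
        mx = x.amax(axis=(2, 3))
        gate = (self._mlp(avg) + self._mlp(mx)).sigmoid()
        return gate.reshape(gate.shape[0], self.channels, 1, 1)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(self.fc1(v).relu())

    def out_shape(self, s):
        return (s[0], 1, 1)

    def macs(self, s):
        # shared MLP evaluated on both pooled descriptors
        per_pass = self.fc1.in_features * self.fc1.out_features + \
            self.fc2.in_features * self.fc2.out_features
        return 2 * per_pass


class SpatialAttention(Module):
    """Sigmoid spatial gate: k x k conv over channel-wise [mean; max] maps."""

    def __init__(self, cfg: CBAMConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        k = cfg.spatial_kernel
        self.conv = Conv2d(2, 1, k, padding=k // 2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.amax(axis=1, keepdims=True)
        return self.conv(Tensor.concat([avg, mx], axis=1)).sigmoid()

    def out_shape(self, s):
        return (1, s[1], s[2])

    def macs(self, s):
        return self.conv.macs((2, s[1], s[2]))


class CBAM(Module):
    """Sequential channel-then-spatial attention; preserves shape."""

    def __init__(self, channels: int, cfg: CBAMConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg if cfg is not None else CBAMConfig()
        self.channel = ChannelAttention(channels, cfg, rng=rng)
        self.spatial = SpatialAttention(cfg, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        xp = x * self.channel(x)       # F'  = M_c(F) (x) F
        return xp * self.spatial(xp)   # F'' = M_s(F') (x) F'

    def out_shape(self, s):
        return tuple(s)

    def macs(self, s):
        return self.channel.macs(s) + self.spatial.macs(s)
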