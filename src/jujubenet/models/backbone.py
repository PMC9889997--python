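"""Backbone assembly.

Both network variants share one skeleton: a 4x4 stride-4 patchify stem with
channel normalization, four stages of residual blocks separated by
(LayerNorm + 2x2 stride-2 conv) downsample layers, a final channel
normalization after global average pooling, and a linear classifier. The
drop-path rate ramps linearly from 0 at the first block to the configured
rate at the last block.

CBAM placement schemes:

* ``scheme_a`` — one CBAM after every residual block;
* ``scheme_b`` — one CBAM before each of the three downsample layers;
* ``scheme_c`` — one CBAM after the stem and after each downsample
  (four insertions, one per stage width); this is the configuration the
  full network uses;
* ``none`` — no attention.
"""

from __future__ import annotations

import numpy as np

from ..nn import (
    Conv2d,
    GlobalAvgPool,
    Identity,
    LayerNorm,
    Linear,
    Module,
    ModuleList,
    Sequential,
    Tensor,
)
from .blocks import CBAM, ConvNeXtBlock, MDCBlock
from .config import CBAMConfig, MDCVariant, ModelConfig, StageConfig

__all__ = ["Backbone", "build_convnext_tiny", "build_jujubenet", "FEATURE_LAYERS"]

FEATURE_LAYERS = ("stem", "stage1", "stage2", "stage3", "stage4")


class Backbone(Module):
    def __init__(self, config: ModelConfig, block_type: str = "convnext", seed: int = 0):
        super().__init__()
        if block_type not in ("convnext", "mdc"):
            raise ValueError(f"unknown block type {block_type!r}")
        self.config = config
        self.block_type = block_type
        sc = config.stage_config
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        scheme = config.cbam_positions

        self.stem = Sequential([
            Conv2d(3, sc.dims[0], 4, stride=4, rng=rng),
            LayerNorm(sc.dims[0], data_format="channels_first"),
        ])
        self.stem_cbam = (
            CBAM(sc.dims[0], config.cbam, rng=rng) if scheme == "scheme_c" else Identity()
        )

        total_blocks = sum(sc.depths)
        dp_rates = np.linspace(0.0, config.drop_path_rate, total_blocks)
        self.stages = ModuleList()
        self.downsamples = ModuleList()
        self.pre_down_cbam = ModuleList()
        self.post_down_cbam = ModuleList()
        k = 0
        for i, (depth, dim) in enumerate(zip(sc.depths, sc.dims)):
            blocks = []
            for _ in range(depth):
                if block_type == "convnext":
                    blk = ConvNeXtBlock(dim, float(dp_rates[k]), config.layer_scale_init, rng=rng)
                else:
                    blk = MDCBlock(dim, config.mdc_variant, float(dp_rates[k]),
                                   config.layer_scale_init, rng=rng)
                blocks.append(blk)
                if scheme == "scheme_a":
                    blocks.append(CBAM(dim, config.cbam, rng=rng))
                k += 1
            self.stages.append(Sequential(blocks))
            if i < 3:
                self.pre_down_cbam.append(
                    CBAM(dim, config.cbam, rng=rng) if scheme == "scheme_b" else Identity()
                )
                self.downsamples.append(Sequential([
                    LayerNorm(dim, data_format="channels_first"),
                    Conv2d(dim, sc.dims[i + 1], 2, stride=2, rng=rng),
                ]))
                self.post_down_cbam.append(
                    CBAM(sc.dims[i + 1], config.cbam, rng=rng)
                    if scheme == "scheme_c" else Identity()
                )

        self.pool = GlobalAvgPool()
        self.norm = LayerNorm(sc.dims[3])
        self.head = Linear(sc.dims[3], config.num_classes, rng=rng)
        self._features: dict[str, Tensor] = {}

    # -- forward --------------------------------------------------------------
    def forward(self, x, capture: tuple = ()) -> Tensor:
        x = Tensor.as_tensor(x)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected input of shape (B, 3, H, W), got {x.shape}")
        H, W = x.shape[2], x.shape[3]
        if H % 32 or W % 32:
            raise ValueError(
                f"input spatial size {H}x{W} must be divisible by 32 "
                f"(stride-4 stem followed by three stride-2 downsamples)"
            )
        self._features = {}
        y = self.stem_cbam(self.stem(x))
        if "stem" in capture:
            self._features["stem"] = y
        for i in range(4):
            y = self.stages[i](y)
            if f"stage{i + 1}" in capture:
                self._features[f"stage{i + 1}"] = y
            if i < 3:
                y = self.pre_down_cbam[i](y)
                y = self.downsamples[i](y)
                y = self.post_down_cbam[i](y)
        return self.head(self.norm(self.pool(y)))

    def feature(self, name: str) -> Tensor:
        return self._features[name]

    # -- shape/MAC accounting -------------------------------------------------
    def out_shape(self, s):
        return (self.config.num_classes,)

    def macs(self, s):
        shape = s
        total = self.stem.macs(shape)
        shape = self.stem.out_shape(shape)
        total += self.stem_cbam.macs(shape)
        for i in range(4):
            total += self.stages[i].macs(shape)
            shape = self.stages[i].out_shape(shape)
            if i < 3:
                total += self.pre_down_cbam[i].macs(shape)
                total += self.downsamples[i].macs(shape)
                shape = self.downsamples[i].out_shape(shape)
                total += self.post_down_cbam[i].macs(shape)
        total += self.head.macs((shape[0],))
        return total

    def layer_summary(self, input_shape=(3, 224, 224)) -> list[dict]:
        """Per-top-level-module name, output shape and parameter count."""
        rows = []
        shape = input_shape
        entries = [("stem", self.stem), ("stem_cbam", self.stem_cbam)]
        for i in range(4):
            entries.append((f"stage{i + 1}", self.stages[i]))
            if i < 3:
                entries.append((f"pre_down_cbam{i + 1}", self.pre_down_cbam[i]))
                entries.append((f"downsample{i + 1}", self.downsamples[i]))
                entries.append((f"post_down_cbam{i + 1}", self.post_down_cbam[i]))
        entries += [("pool", self.pool), ("norm", self.norm), ("head", self.head)]
        for name, mod in entries:
            shape = mod.out_shape(shape)
            rows.append({
                "layer": name,
                "output_shape": list(shape),
                "params": mod.param_count(),
            })
        return rows


def build_convnext_tiny(
    num_classes: int = 6,
    stage_config: StageConfig | None = None,
    drop_path_rate: float = 0.1,
    layer_scale_init: float = 1e-6,
    cbam_positions: str = "none",
    cbam: CBAMConfig | None = None,
    seed: int = 0,
) -> Backbone:
    """Reference ConvNeXt-Tiny classifier (optionally with CBAM insertions)."""
    config = ModelConfig(
        num_classes=num_classes,
        stage_config=stage_config or StageConfig(),
        cbam=cbam or CBAMConfig(),
        drop_path_rate=drop_path_rate,
        layer_scale_init=layer_scale_init,
        cbam_positions=cbam_positions,
    )
    return Backbone(config, block_type="convnext", seed=seed)


def build_jujubenet(config: ModelConfig | None = None, seed: int = 0,
                    variant: MDCVariant | None = None) -> Backbone:
    """Lightweight network: MDC blocks in the ConvNeXt-Tiny skeleton + CBAM."""
    if config is None:
        config = ModelConfig(mdc_variant=variant or MDCVariant())
    elif variant is not None:
        raise ValueError("pass the variant inside config, or config=None")
    return Backbone(config, block_type="mdc", seed=seed)
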