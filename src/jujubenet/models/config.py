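"""Configuration types for the network family.

The backbone follows the ConvNeXt-Tiny skeleton: a 4x4/4 patchify stem, four
stages of residual blocks, 2x2/2 downsample layers between stages, global
average pooling and a linear classifier. The residual block is either the
standard ConvNeXt block or the lightweight two-branch MDC block; CBAM
attention modules can be inserted at several positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["StageConfig", "MDCVariant", "CBAMConfig", "ModelConfig"]

BRANCH_A_EXPANSIONS = (2, 4)
BRANCH_B_KERNELS = (3, 5, 7)
BRANCH_B_POINTWISE = ("per_conv", "single_final", "none")
CBAM_POSITIONS = ("scheme_a", "scheme_b", "scheme_c", "none")


@dataclass(frozen=True)
class StageConfig:
    """Blocks per stage and channel width per stage."""

    depths: tuple[int, int, int, int] = (3, 3, 9, 3)
    dims: tuple[int, int, int, int] = (96, 192, 384, 768)

    def __post_init__(self):
        if len(self.depths) != 4 or len(self.dims) != 4:
            raise ValueError("depths and dims must each have 4 entries")
        if any(d < 1 for d in self.depths):
            raise ValueError("all stage depths must be positive")
        if any(c < 1 or c % 2 for c in self.dims):
            raise ValueError("all stage dims must be positive and even (channel split)")
        if list(self.dims) != sorted(set(self.dims)):
            raise ValueError("stage dims must be strictly increasing")


@dataclass(frozen=True)
class MDCVariant:
    """Free choices in the two-branch block left open by its block diagram.

    branch_a_expansion
        MLP expansion factor of the ConvNeXt-style branch (relative to the
        half-width branch channels).
    branch_b_kernel
        Depthwise kernel size of the wide-residual branch.
    branch_b_pointwise
        Where the 1x1 channel-mixing convolution sits in the wide-residual
        branch: after each depthwise conv, once at the end, or nowhere.
    """

    branch_a_expansion: int = 4
    branch_b_kernel: int = 5
    branch_b_pointwise: str = "none"

    def __post_init__(self):
        if self.branch_a_expansion not in BRANCH_A_EXPANSIONS:
            raise ValueError(f"branch_a_expansion must be in {BRANCH_A_EXPANSIONS}")
        if self.branch_b_kernel not in BRANCH_B_KERNELS:
            raise ValueError(f"branch_b_kernel must be in {BRANCH_B_KERNELS}")
        if self.branch_b_pointwise not in BRANCH_B_POINTWISE:
            raise ValueError(f"branch_b_pointwise must be in {BRANCH_B_POINTWISE}")

    @staticmethod
    def full_family() -> list["MDCVariant"]:
        """The enumerable 2 x 3 x 3 candidate grid."""
        return [
            MDCVariant(e, k, pw)
            for e in BRANCH_A_EXPANSIONS
            for k in BRANCH_B_KERNELS
            for pw in BRANCH_B_POINTWISE
        ]


@dataclass(frozen=True)
class CBAMConfig:
    """Channel-attention bottleneck ratio and spatial-attention kernel."""

    reduction_ratio: int = 16
    spatial_kernel: int = 7

    def __post_init__(self):
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be positive")
        if self.spatial_kernel < 1 or self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd and positive")


@dataclass(frozen=True)
class ModelConfig:
    num_classes: int = 6
    stage_config: StageConfig = field(default_factory=StageConfig)
    mdc_variant: MDCVariant = field(default_factory=MDCVariant)
    cbam: CBAMConfig = field(default_factory=CBAMConfig)
    drop_path_rate: float = 0.1
    layer_scale_init: float = 1e-6
    cbam_positions: str = "scheme_c"

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be at least 2")
        if not 0.0 <= self.drop_path_rate < 1.0:
            raise ValueError("drop_path_rate must lie in [0, 1)")
        if self.layer_scale_init < 0:
            raise ValueError("layer_scale_init must be non-negative")
        if self.cbam_positions not in CBAM_POSITIONS:
            raise ValueError(f"cbam_positions must be in {CBAM_POSITIONS}")
        if self.cbam_positions != "none":
            r = self.cbam.reduction_ratio
            if any(d % r for d in self.stage_config.dims):
                raise ValueError(
                    f"CBAM reduction ratio {r} must divide every stage dim "
                    f"{self.stage_config.dims}"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "ModelConfig":
        d = dict(d)
        if "stage_config" in d and isinstance(d["stage_config"], dict):
            sc = d["stage_config"]
            d["stage_config"] = StageConfig(tuple(sc["depths"]), tuple(sc["dims"]))
        if "mdc_variant" in d and isinstance(d["mdc_variant"], dict):
            d["mdc_variant"] = MDCVariant(**d["mdc_variant"])
        if "cbam" in d and isinstance(d["cbam"], dict):
            d["cbam"] = CBAMConfig(**d["cbam"])
        return ModelConfig(**d)
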