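"""Analytic architecture descriptions of reference classifiers.

For the published comparison table the package needs trainable-parameter and
multiply-accumulate counts of the standard baselines (ResNet-18/34/50,
DenseNet-121, Swin-Tiny, VGG-16, SqueezeNet-1.1) with the classifier head
sized to the task's class count. These are computed from exact layer-by-layer
descriptions of the canonical architectures rather than from instantiated
weights: every trainable scalar and every conv/linear multiply-accumulate is
enumerated. Batch-norm running statistics are buffers, not parameters, and
contribute nothing.

Counting conventions (shared with :mod:`jujubenet.model_stats`):

* conv MACs = k^2 * C_in / groups * C_out * H_out * W_out;
* linear MACs = fan_in * fan_out per spatial position / token;
* normalization, activation and pooling ops are not counted;
* attention score/value matmuls of window attention are reported in
  ``uncounted`` instead of being silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ArchDescription", "describe", "ZOO_NAMES"]

ZOO_NAMES = (
    "resnet18",
    "resnet34",
    "resnet50",
    "densenet121",
    "swin_tiny",
    "vgg16",
    "squeezenet1_1",
    "convnext_tiny",
)


@dataclass
class ArchDescription:
    """Layer-by-layer (name, params, macs) ledger of an architecture."""

    name: str
    input_size: int
    layers: list = field(default_factory=list)
    uncounted: list = field(default_factory=list)
    _hw: int = 0
    _channels: int = 0

    # -- construction helpers -------------------------------------------------
    def conv(self, tag, cin, cout, k, stride=1, padding=0, groups=1, bias=True):
        hw = (self._hw + 2 * padding - k) // stride + 1
        params = k * k * (cin // groups) * cout + (cout if bias else 0)
        macs = k * k * (cin // groups) * cout * hw * hw
        self.layers.append((tag, params, macs))
        self._hw, self._channels = hw, cout
        return self

    def bn(self, tag, c):
        self.layers.append((tag, 2 * c, 0))
        return self

    def ln(self, tag, c):
        self.layers.append((tag, 2 * c, 0))
        return self

    def linear(self, tag, fin, fout, tokens=1, bias=True):
        self.layers.append((tag, fin * fout + (fout if bias else 0), fin * fout * tokens))
        return self

    def table(self, tag, n):
        """A plain trainable table (e.g. relative position bias)."""
        self.layers.append((tag, n, 0))
        return self

    def pool(self, k, stride=None, padding=0):
        stride = stride or k
        self._hw = (self._hw + 2 * padding - k) // stride + 1
        return self

    # -- reports --------------------------------------------------------------
    def param_count(self) -> int:
        return sum(p for _, p, _ in self.layers)

    def mac_count(self) -> int:
        return sum(m for _, _, m in self.layers)

    def param_items(self):
        return [(tag, p) for tag, p, _ in self.layers]


# ---------------------------------------------------------------------------
# ResNet family
# ---------------------------------------------------------------------------

def _resnet(d: ArchDescription, layers, bottleneck: bool, num_classes: int):
    d._hw = d.input_size
    d.conv("conv1", 3, 64, 7, stride=2, padding=3, bias=False).bn("bn1", 64)
    d.pool(3, 2, 1)
    cin = 64
    expansion = 4 if bottleneck else 1
    for stage, (n, mid) in enumerate(zip(layers, (64, 128, 256, 512))):
        for b in range(n):
            stride = 2 if (stage > 0 and b == 0) else 1
            cout = mid * expansion
            tag = f"layer{stage + 1}.{b}"
            if bottleneck:
                d.conv(f"{tag}.conv1", cin, mid, 1, bias=False).bn(f"{tag}.bn1", mid)
                d.conv(f"{tag}.conv2", mid, mid, 3, stride=stride, padding=1, bias=False)
                d.bn(f"{tag}.bn2", mid)
                d.conv(f"{tag}.conv3", mid, cout, 1, bias=False).bn(f"{tag}.bn3", cout)
            else:
                d.conv(f"{tag}.conv1", cin, mid, 3, stride=stride, padding=1, bias=False)
                d.bn(f"{tag}.bn1", mid)
                d.conv(f"{tag}.conv2", mid, cout, 3, padding=1, bias=False)
                d.bn(f"{tag}.bn2", cout)
            if stride != 1 or cin != cout:
                hw_saved = d._hw
                d._hw = hw_saved * stride  # shortcut conv sees the block input
                d.conv(f"{tag}.downsample", cin, cout, 1, stride=stride, bias=False)
                d.bn(f"{tag}.downsample.bn", cout)
                d._hw = hw_saved
            cin = cout
    d.linear("fc", cin, num_classes)
    return d


# ---------------------------------------------------------------------------
# DenseNet-121
# ---------------------------------------------------------------------------

def _densenet121(d: ArchDescription, num_classes: int, growth=32, init_features=64):
    d._hw = d.input_size
    d.conv("conv0", 3, init_features, 7, stride=2, padding=3, bias=False)
    d.bn("norm0", init_features)
    d.pool(3, 2, 1)
    c = init_features
    for i, n in enumerate((6, 12, 24, 16)):
        for b in range(n):
            tag = f"denseblock{i + 1}.denselayer{b + 1}"
            d.bn(f"{tag}.norm1", c)
            d.conv(f"{tag}.conv1", c, 4 * growth, 1, bias=False)
            d.bn(f"{tag}.norm2", 4 * growth)
            d.conv(f"{tag}.conv2", 4 * growth, growth, 3, padding=1, bias=False)
            c += growth
        if i < 3:
            d.bn(f"transition{i + 1}.norm", c)
            d.conv(f"transition{i + 1}.conv", c, c // 2, 1, bias=False)
            d.pool(2, 2)
            c //= 2
    d.bn("norm5", c)
    d.linear("classifier", c, num_classes)
    return d


# ---------------------------------------------------------------------------
# Swin-Tiny (window 7, patch 4)
# ---------------------------------------------------------------------------

def _swin_tiny(d: ArchDescription, num_classes: int):
    depths, dims, window = (2, 2, 6, 2), (96, 192, 384, 768), 7
    d._hw = d.input_size
    d.conv("patch_embed", 3, dims[0], 4, stride=4)
    d.ln("patch_embed.norm", dims[0])
    for i, (depth, c) in enumerate(zip(depths, dims)):
        heads = c // 32
        tokens = d._hw * d._hw
        for b in range(depth):
            tag = f"layers{i}.block{b}"
            d.ln(f"{tag}.norm1", c)
            d.linear(f"{tag}.attn.qkv", c, 3 * c, tokens)
            d.table(f"{tag}.attn.rel_pos_bias", (2 * window - 1) ** 2 * heads)
            d.linear(f"{tag}.attn.proj", c, c, tokens)
            d.ln(f"{tag}.norm2", c)
            d.linear(f"{tag}.mlp.fc1", c, 4 * c, tokens)
            d.linear(f"{tag}.mlp.fc2", 4 * c, c, tokens)
            d.uncounted.append(f"{tag}.attn window matmuls (QK^T, attn@V)")
        if i < 3:
            d.ln(f"layers{i}.downsample.norm", 4 * c)
            # patch merging: 2x2 neighborhood concat then linear 4C -> 2C
            d._hw //= 2
            d.linear(f"layers{i}.downsample.reduction", 4 * c, 2 * c,
                     d._hw * d._hw, bias=False)
    d.ln("norm", dims[3])
    d.linear("head", dims[3], num_classes)
    return d


# ---------------------------------------------------------------------------
# VGG-16 and SqueezeNet-1.1
# ---------------------------------------------------------------------------

def _vgg16(d: ArchDescription, num_classes: int):
    d._hw = d.input_size
    cfg = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512, "M",
           512, 512, 512, "M"]
    cin, idx = 3, 0
    for v in cfg:
        if v == "M":
            d.pool(2, 2)
            continue
        d.conv(f"features.{idx}", cin, v, 3, padding=1)
        cin, idx = v, idx + 1
    d.linear("classifier.0", 512 * 7 * 7, 4096)
    d.linear("classifier.3", 4096, 4096)
    d.linear("classifier.6", 4096, num_classes)
    return d


def _squeezenet1_1(d: ArchDescription, num_classes: int):
    d._hw = d.input_size
    d.conv("conv1", 3, 64, 3, stride=2)
    d.pool(3, 2)
    fires = [
        (64, 16, 64, 64), (128, 16, 64, 64), "M",
        (128, 32, 128, 128), (256, 32, 128, 128), "M",
        (256, 48, 192, 192), (384, 48, 192, 192),
        (384, 64, 256, 256), (512, 64, 256, 256),
    ]
    i = 2
    for f in fires:
        if f == "M":
            d.pool(3, 2)
            continue
        cin, s1, e1, e3 = f
        d.conv(f"fire{i}.squeeze", cin, s1, 1)
        hw = d._hw
        d.conv(f"fire{i}.expand1x1", s1, e1, 1)
        d._hw = hw
        d.conv(f"fire{i}.expand3x3", s1, e3, 3, padding=1)
        d._channels = e1 + e3
        i += 1
    d.conv("classifier.conv", 512, num_classes, 1)
    return d


# ---------------------------------------------------------------------------
# ConvNeXt-Tiny (analytic cross-check of the live implementation)
# ---------------------------------------------------------------------------

def _convnext_tiny(d: ArchDescription, num_classes: int):
    depths, dims = (3, 3, 9, 3), (96, 192, 384, 768)
    d._hw = d.input_size
    d.conv("stem.conv", 3, dims[0], 4, stride=4)
    d.ln("stem.norm", dims[0])
    for i, (depth, c) in enumerate(zip(depths, dims)):
        tokens = d._hw * d._hw
        for b in range(depth):
            tag = f"stage{i + 1}.block{b}"
            d.conv(f"{tag}.dwconv", c, c, 7, padding=3, groups=c)
            d.ln(f"{tag}.norm", c)
            d.linear(f"{tag}.pwconv1", c, 4 * c, tokens)
            d.linear(f"{tag}.pwconv2", 4 * c, c, tokens)
            d.table(f"{tag}.layer_scale", c)
        if i < 3:
            d.ln(f"downsample{i + 1}.norm", c)
            d.conv(f"downsample{i + 1}.conv", c, dims[i + 1], 2, stride=2)
    d.ln("norm", dims[3])
    d.linear("head", dims[3], num_classes)
    return d


_BUILDERS = {
    "resnet18": lambda d, n: _resnet(d, (2, 2, 2, 2), False, n),
    "resnet34": lambda d, n: _resnet(d, (3, 4, 6, 3), False, n),
    "resnet50": lambda d, n: _resnet(d, (3, 4, 6, 3), True, n),
    "densenet121": _densenet121,
    "swin_tiny": _swin_tiny,
    "vgg16": _vgg16,
    "squeezenet1_1": _squeezenet1_1,
    "convnext_tiny": _convnext_tiny,
}


def describe(name: str, num_classes: int = 6, input_size: int = 224) -> ArchDescription:
    """Build the analytic description of a reference architecture."""
    if name not in _BUILDERS:
        raise ValueError(f"unknown architecture {name!r}; choose from {sorted(_BUILDERS)}")
    d = ArchDescription(name=name, input_size=input_size)
    return _BUILDERS[name](d, num_classes)
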