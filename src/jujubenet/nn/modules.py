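"""Neural-network building blocks on top of the autograd core.

Layout convention is NCHW (channels first), as in the ConvNeXt family.
``LayerNorm`` normalizes over the channel axis; for channels-first inputs it
permutes to channels-last internally. Weights are initialized from a
truncated normal (sigma = 0.02, clipped at 2 sigma) with zero biases.
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Identity",
    "Conv2d",
    "Linear",
    "LayerNorm",
    "GELU",
    "DropPath",
    "GlobalAvgPool",
    "trunc_normal",
]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated-normal draws, resampling values beyond 2 standard deviations."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x.astype(np.float32)


class Module:
    """Base class: child discovery via ``__dict__``, train/eval mode, counting."""

    def __init__(self):
        self.training = True

    # -- traversal ------------------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def modules(self):
        yield self
        for _, child in self.children():
            yield from (m for m in child.modules())

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield (prefix + name, value)
        for name, child in self.children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- modes ----------------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def seed_stochastic(self, seed: int):
        """Re-seed every stochastic sub-module (drop path) deterministically."""
        ss = np.random.SeedSequence(seed)
        for m in self.modules():
            if isinstance(m, DropPath):
                m.rng = np.random.default_rng(ss.spawn(1)[0])
        return self

    # -- state dict -----------------------------------------------------------
    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    # MAC accounting (multiply-accumulates for one forward pass); modules that
    # do no multiply-accumulate work inherit the zero default.
    def macs(self, input_shape: tuple) -> int:
        total = 0
        for _, child in self.children():
            total += child.macs(input_shape)
            input_shape = child.out_shape(input_shape)
        return total

    def out_shape(self, input_shape: tuple) -> tuple:
        for _, child in self.children():
            input_shape = child.out_shape(input_shape)
        return input_shape


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)

    def append(self, m: Module):
        setattr(self, str(len(list(self.children()))), m)

    def __iter__(self):
        return (m for _, m in self.children())

    def __len__(self):
        return sum(1 for _ in self.children())

    def __getitem__(self, i: int):
        return getattr(self, str(i))


class Sequential(ModuleList):
    def forward(self, x: Tensor) -> Tensor:
        for m in self:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.stride, self.padding, self.groups = kernel_size, stride, padding, groups
        self.weight = Parameter(
            trunc_normal(rng, (out_channels, in_channels // groups, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding, self.groups)

    def out_shape(self, s):
        c, h, w = s
        k, st, p = self.kernel_size, self.stride, self.padding
        return (self.out_channels, (h + 2 * p - k) // st + 1, (w + 2 * p - k) // st + 1)

    def macs(self, s):
        _, ho, wo = self.out_shape(s)
        per_pos = self.kernel_size**2 * (self.in_channels // self.groups) * self.out_channels
        return per_pos * ho * wo


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_features, self.out_features = in_features, out_features
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.linear(self.weight, self.bias)

    def out_shape(self, s):
        return tuple(s[:-1]) + (self.out_features,)

    def macs(self, s):
        lead = int(np.prod(s[:-1])) if len(s) > 1 else 1
        return lead * self.in_features * self.out_features


class LayerNorm(Module):
    """Layer normalization over the channel axis.

    ``data_format='channels_last'`` expects the channel axis last and
    normalizes in place; ``'channels_first'`` accepts NCHW maps and permutes
    around the normalization.
    """

    def __init__(self, num_features: int, eps: float = 1e-6, data_format: str = "channels_last"):
        super().__init__()
        if data_format not in ("channels_last", "channels_first"):
            raise ValueError(f"unknown data_format {data_format!r}")
        self.num_features = num_features
        self.eps = eps
        self.data_format = data_format
        self.weight = Parameter(np.ones(num_features, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.data_format == "channels_last":
            return x.layer_norm(self.weight, self.bias, self.eps)
        perm = (0, 2, 3, 1)
        y = x.transpose(*perm).layer_norm(self.weight, self.bias, self.eps)
        return y.transpose(0, 3, 1, 2)

    def out_shape(self, s):
        return tuple(s)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()

    def out_shape(self, s):
        return tuple(s)


class GlobalAvgPool(Module):
    """NCHW -> NC spatial mean."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))

    def out_shape(self, s):
        return (s[0],)


class DropPath(Module):
    """Stochastic depth: zero a residual branch per sample while training.

    The surviving samples are rescaled by 1/(1-rate) so the expectation is
    unchanged. Identity in evaluation mode or at rate 0.
    """

    def __init__(self, rate: float = 0.0):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"drop-path rate must lie in [0, 1), got {rate}")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        shape = (x.shape[0],) + (1,) * (x.ndim - 1)
        mask = (self.rng.random(shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)

    def out_shape(self, s):
        return tuple(s)
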