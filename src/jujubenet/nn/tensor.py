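"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package trains small convolutional networks on CPU; this module provides
exactly the primitives those networks need (convolution with groups, linear
maps, layer normalization, GELU/sigmoid gates, pooling reductions and a fused
softmax cross-entropy) as nodes of a dynamically built computation graph.
Gradients are propagated by :meth:`Tensor.backward` in reverse topological
order; every node in the graph receives a ``.grad`` so that intermediate
activations can be inspected (needed for Grad-CAM).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = ["Tensor", "Parameter", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- bookkeeping ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; recursion depth would scale with net depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in node._backward(g):
                if not parent.requires_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def back(g):
            return [(a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape))]

        return Tensor._make(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: [(a, -g)])

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        a, b = self, other

        def back(g):
            return [
                (a, _unbroadcast(g * b.data, a.data.shape)),
                (b, _unbroadcast(g * a.data, b.data.shape)),
            ]

        return Tensor._make(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (Tensor.as_tensor(other) ** -1.0)

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)
        out_data = a.data**e

        def back(g):
            return [(a, g * e * a.data ** (e - 1.0))]

        return Tensor._make(out_data, (a,), back)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        orig = a.data.shape
        return Tensor._make(a.data.reshape(*shape), (a,), lambda g: [(a, g.reshape(orig))])

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)
        return Tensor._make(
            np.ascontiguousarray(a.data.transpose(*axes)),
            (a,),
            lambda g: [(a, g.transpose(*inv))],
        )

    def narrow(self, axis: int, start: int, length: int):
        """Slice ``length`` entries from ``start`` along ``axis``."""
        a = self
        sl = [slice(None)] * a.data.ndim
        sl[axis] = slice(start, start + length)
        sl = tuple(sl)

        def back(g):
            full = np.zeros_like(a.data)
            full[sl] = g
            return [(a, full)]

        return Tensor._make(np.ascontiguousarray(a.data[sl]), (a,), back)

    @staticmethod
    def concat(tensors: list, axis: int = 1):
        tensors = [Tensor.as_tensor(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def back(g):
            out = []
            for t, s, e in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(s), int(e))
                out.append((t, np.ascontiguousarray(g[tuple(sl)])))
            return out

        return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, back)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                return [(a, np.broadcast_to(g, a.data.shape).astype(np.float32))]
            g2 = g if keepdims else np.expand_dims(g, axis)
            return [(a, np.broadcast_to(g2, a.data.shape).astype(np.float32))]

        return Tensor._make(out_data, (a,), back)

    def mean(self, axis=None, keepdims: bool = False):
        a = self
        n = a.data.size if axis is None else np.prod(
            [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def amax(self, axis, keepdims: bool = False):
        """Max over ``axis``; ties share the incoming gradient equally."""
        a = self
        out_data = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == out_data).astype(np.float32)
        mask /= mask.sum(axis=axis, keepdims=True)

        def back(g):
            g2 = g if keepdims else np.expand_dims(g, axis)
            return [(a, mask * g2)]

        res = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return Tensor._make(res, (a,), back)

    # -- pointwise nonlinearities ---------------------------------------------
    def gelu(self):
        a = self
        x = a.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0, dtype=np.float32)))
        out_data = (x * cdf).astype(np.float32)
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)

        def back(g):
            return [(a, g * (cdf + x * pdf).astype(np.float32))]

        return Tensor._make(out_data, (a,), back)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(s, (a,), lambda g: [(a, g * s * (1.0 - s))])

    def relu(self):
        a = self
        mask = (a.data > 0).astype(np.float32)
        return Tensor._make(a.data * mask, (a,), lambda g: [(a, g * mask)])

    # -- linear algebra -------------------------------------------------------
    def linear(self, weight: "Tensor", bias: "Tensor | None" = None):
        """``y = x @ W + b`` with ``x: (..., in)``, ``W: (in, out)``."""
        a, w = self, weight
        lead = a.data.shape[:-1]
        x2 = a.data.reshape(-1, a.data.shape[-1])
        y = x2 @ w.data
        if bias is not None:
            y = y + bias.data
        parents = (a, w) if bias is None else (a, w, bias)

        def back(g):
            g2 = g.reshape(-1, g.shape[-1])
            out = [
                (a, (g2 @ w.data.T).reshape(a.data.shape)),
                (w, x2.T @ g2),
            ]
            if bias is not None:
                out.append((bias, g2.sum(axis=0)))
            return out

        return Tensor._make(y.reshape(*lead, w.data.shape[1]), parents, back)

    def conv2d(
        self,
        weight: "Tensor",
        bias: "Tensor | None" = None,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
    ):
        """2-D convolution (cross-correlation) in NCHW layout with groups."""
        a, w = self, weight
        B, Cin, H, W = a.data.shape
        Cout, Cin_g, kh, kw = w.data.shape
        if Cin % groups or Cout % groups or Cin // groups != Cin_g:
            raise ValueError(
                f"channel/group mismatch: input {Cin} channels, weight expects "
                f"{Cin_g} per group with {groups} groups"
            )
        s, p = int(stride), int(padding)
        xp = np.pad(a.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else a.data
        Hp, Wp = xp.shape[2], xp.shape[3]
        Hout, Wout = (Hp - kh) // s + 1, (Wp - kw) // s + 1
        if Hout < 1 or Wout < 1:
            raise ValueError(f"kernel {kh}x{kw} larger than padded input {Hp}x{Wp}")
        # (B, Cin, Hout, Wout, kh, kw) strided view of all receptive fields
        patches = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
        pv = patches.reshape(B, groups, Cin_g, Hout, Wout, kh, kw)
        wv = w.data.reshape(groups, Cout // groups, Cin_g, kh, kw)
        out = np.einsum("bgihwkl,goikl->bgohw", pv, wv, optimize=True)
        out = np.ascontiguousarray(out.reshape(B, Cout, Hout, Wout))
        if bias is not None:
            out += bias.data.reshape(1, Cout, 1, 1)
        parents = (a, w) if bias is None else (a, w, bias)

        def back(g):
            gv = g.reshape(B, groups, Cout // groups, Hout, Wout)
            gw = np.einsum("bgihwkl,bgohw->goikl", pv, gv, optimize=True)
            gpatch = np.einsum("goikl,bgohw->bgihwkl", wv, gv, optimize=True)
            gpatch = gpatch.reshape(B, Cin, Hout, Wout, kh, kw)
            gx = np.zeros((B, Cin, Hp, Wp), dtype=np.float32)
            for i in range(kh):  # scatter-add column gradients back (col2im)
                for j in range(kw):
                    gx[:, :, i : i + s * Hout : s, j : j + s * Wout : s] += gpatch[:, :, :, :, i, j]
            if p:
                gx = gx[:, :, p : p + H, p : p + W]
            out_grads = [(a, np.ascontiguousarray(gx)), (w, gw.reshape(w.data.shape))]
            if bias is not None:
                out_grads.append((bias, g.sum(axis=(0, 2, 3))))
            return out_grads

        return Tensor._make(out, parents, back)

    def layer_norm(self, weight: "Tensor", bias: "Tensor", eps: float = 1e-6):
        """Normalize over the last axis, then apply a per-feature affine map."""
        a, w, b = self, weight, bias
        x = a.data
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        out = y * w.data + b.data

        def back(g):
            gy = g * w.data
            gmean = gy.mean(axis=-1, keepdims=True)
            gymean = (gy * y).mean(axis=-1, keepdims=True)
            gx = inv * (gy - gmean - y * gymean)
            red = tuple(range(g.ndim - 1))
            return [
                (a, gx.astype(np.float32)),
                (w, (g * y).sum(axis=red)),
                (b, g.sum(axis=red)),
            ]

        return Tensor._make(out, (a, w, b), back)

    def softmax_cross_entropy(self, labels: np.ndarray):
        """Mean cross-entropy between logits ``(B, K)`` and integer labels."""
        a = self
        z = a.data - a.data.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        B = a.data.shape[0]
        idx = (np.arange(B), np.asarray(labels))
        loss = -np.mean(np.log(probs[idx] + 1e-12))

        def back(g):
            gz = probs.copy()
            gz[idx] -= 1.0
            return [(a, (float(g) / B) * gz)]

        return Tensor._make(np.float32(loss), (a,), back)


class Parameter(Tensor):
    """A trainable tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
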