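"""Independent brute-force reference implementations.

These deliberately re-derive every block as explicit per-position loops over
float64 NumPy arrays, sharing no code with the package's vectorized forward
passes; the tests compare the two routes on small random inputs.
"""

import numpy as np
from scipy.special import erf


def np_gelu(x):
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def np_layernorm(v, w, b, eps=1e-6):
    mu = v.mean()
    var = ((v - mu) ** 2).mean()
    return (v - mu) / np.sqrt(var + eps) * w + b


def naive_conv2d(x, w, b=None, stride=1, padding=0, groups=1):
    """Direct convolution loops. x: (C,H,W); w: (Cout, Cin/g, k, k)."""
    C, H, W = x.shape
    Cout, cin_g, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    out = np.zeros((Cout, Ho, Wo))
    cpg_out = Cout // groups
    for o in range(Cout):
        g = o // cpg_out
        for i in range(Ho):
            for j in range(Wo):
                acc = 0.0
                for c in range(cin_g):
                    cin = g * cin_g + c
                    patch = xp[cin, i * stride : i * stride + kh, j * stride : j * stride + kw]
                    acc += float((patch * w[o, c]).sum())
                out[o, i, j] = acc + (b[o] if b is not None else 0.0)
    return out


def _mlp_positionwise(y, norm_w, norm_b, w1, b1, w2, b2, gamma):
    """LayerNorm -> linear -> GELU -> linear -> layer scale, per position."""
    C, H, W = y.shape
    out = np.zeros_like(y)
    for i in range(H):
        for j in range(W):
            v = np_layernorm(y[:, i, j], norm_w, norm_b)
            v = np_gelu(v @ w1 + b1)
            v = v @ w2 + b2
            out[:, i, j] = v * gamma
    return out


def naive_convnext_block(x, blk):
    """Reference forward of a ConvNeXt block (evaluation mode)."""
    C = x.shape[0]
    y = naive_conv2d(x.astype(np.float64), blk.dwconv.weight.data.astype(np.float64),
                     blk.dwconv.bias.data.astype(np.float64), padding=3, groups=C)
    branch = _mlp_positionwise(
        y,
        blk.norm.weight.data.astype(np.float64), blk.norm.bias.data.astype(np.float64),
        blk.pwconv1.weight.data.astype(np.float64), blk.pwconv1.bias.data.astype(np.float64),
        blk.pwconv2.weight.data.astype(np.float64), blk.pwconv2.bias.data.astype(np.float64),
        blk.gamma.data.astype(np.float64),
    )
    return x + branch


def naive_mdc_block(x, blk):
    """Reference forward of the two-branch MDC block (evaluation mode)."""
    c = blk.half
    xa, xb = x[:c].astype(np.float64), x[c:].astype(np.float64)
    ya = naive_conv2d(xa, blk.a_dwconv.weight.data.astype(np.float64),
                      blk.a_dwconv.bias.data.astype(np.float64), padding=3, groups=c)
    ya = _mlp_positionwise(
        ya,
        blk.a_norm.weight.data.astype(np.float64), blk.a_norm.bias.data.astype(np.float64),
        blk.a_pwconv1.weight.data.astype(np.float64), blk.a_pwconv1.bias.data.astype(np.float64),
        blk.a_pwconv2.weight.data.astype(np.float64), blk.a_pwconv2.bias.data.astype(np.float64),
        blk.a_gamma.data.astype(np.float64),
    )
    # branch B: entry norm, depthwise pair with GELU, optional pointwise mixes
    k = blk.variant.branch_b_kernel
    yb = np.zeros_like(xb)
    for i in range(xb.shape[1]):
        for j in range(xb.shape[2]):
            yb[:, i, j] = np_layernorm(xb[:, i, j], blk.b_norm.weight.data.astype(np.float64),
                                       blk.b_norm.bias.data.astype(np.float64))
    yb = np_gelu(naive_conv2d(yb, blk.b_dw1.weight.data.astype(np.float64),
                              blk.b_dw1.bias.data.astype(np.float64), padding=k // 2, groups=c))
    if hasattr(blk, "b_pw1"):
        yb = naive_conv2d(yb, blk.b_pw1.weight.data.astype(np.float64),
                          blk.b_pw1.bias.data.astype(np.float64))
    yb = np_gelu(naive_conv2d(yb, blk.b_dw2.weight.data.astype(np.float64),
                              blk.b_dw2.bias.data.astype(np.float64), padding=k // 2, groups=c))
    if hasattr(blk, "b_pw2"):
        yb = naive_conv2d(yb, blk.b_pw2.weight.data.astype(np.float64),
                          blk.b_pw2.bias.data.astype(np.float64))
    yb = yb * blk.b_gamma.data.astype(np.float64)[:, None, None]
    return x + np.concatenate([ya, yb], axis=0)


def naive_cbam(x, mod):
    """Reference forward of channel-then-spatial attention."""
    x = x.astype(np.float64)

    def mlp(v):
        h = v @ mod.channel.fc1.weight.data.astype(np.float64) + mod.channel.fc1.bias.data
        h = np.maximum(h, 0.0)
        return h @ mod.channel.fc2.weight.data.astype(np.float64) + mod.channel.fc2.bias.data

    avg = x.mean(axis=(1, 2))
    mx = x.max(axis=(1, 2))
    gate_c = 1.0 / (1.0 + np.exp(-(mlp(avg) + mlp(mx))))
    xp = x * gate_c[:, None, None]
    stack = np.stack([xp.mean(axis=0), xp.max(axis=0)])
    k = mod.spatial.conv.kernel_size
    conv = naive_conv2d(stack, mod.spatial.conv.weight.data.astype(np.float64),
                        mod.spatial.conv.bias.data.astype(np.float64), padding=k // 2)
    gate_s = 1.0 / (1.0 + np.exp(-conv[0]))
    return xp * gate_s[None]
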