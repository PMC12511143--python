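"""Literal, unoptimised reference implementations used as oracles.

Everything here is written with explicit Python loops over output positions
and is deliberately independent of the autograd engine's vectorised paths.
"""

import numpy as np


def naive_conv2d(x, w, stride=1, padding=0, groups=1):
    """x (C,H,W), w (O, C/groups, kh, kw) -> (O, OH, OW); zero padding."""
    C, H, W = x.shape
    O, Cg, kh, kw = w.shape
    xp = np.zeros((C, H + 2 * padding, W + 2 * padding), dtype=np.float64)
    xp[:, padding : padding + H, padding : padding + W] = x
    OH = (H + 2 * padding - kh) // stride + 1
    OW = (W + 2 * padding - kw) // stride + 1
    out = np.zeros((O, OH, OW))
    per_out = O // groups
    for o in range(O):
        g = o // per_out
        for i in range(OH):
            for j in range(OW):
                acc = 0.0
                for c in range(Cg):
                    for u in range(kh):
                        for v in range(kw):
                            acc += xp[g * Cg + c, i * stride + u, j * stride + v] * w[o, c, u, v]
                out[o, i, j] = acc
    return out


def naive_maxpool2d(x, k, stride=1, padding=0):
    C, H, W = x.shape
    xp = np.full((C, H + 2 * padding, W + 2 * padding), -np.inf)
    xp[:, padding : padding + H, padding : padding + W] = x
    OH = (H + 2 * padding - k) // stride + 1
    OW = (W + 2 * padding - k) // stride + 1
    out = np.zeros((C, OH, OW))
    for c in range(C):
        for i in range(OH):
            for j in range(OW):
                out[c, i, j] = xp[c, i * stride : i * stride + k, j * stride : j * stride + k].max()
    return out


def naive_bn_eval(x, bn):
    """Eval-mode batch norm of a Conv block, per channel, loops included."""
    out = np.empty_like(x, dtype=np.float64)
    for c in range(x.shape[0]):
        out[c] = (
            (x[c] - bn.running_mean[c]) / np.sqrt(bn.running_var[c] + bn.eps)
        ) * bn.gamma.data[c] + bn.beta.data[c]
    return out


def silu(x):
    return x / (1.0 + np.exp(-x))


def naive_conv_block(x, block):
    """Conv+BN+SiLU reference (eval mode)."""
    y = naive_conv2d(x, block.conv.weight.data.astype(np.float64),
                     block.conv.stride, block.conv.padding, block.conv.groups)
    y = naive_bn_eval(y, block.bn)
    return silu(y) if block.act else y


def naive_giconv(x, module):
    """Literal GIConv forward (eval mode) from the module's own parameters."""
    core = naive_conv_block(x, module.primary)
    m = module.mixer
    y1 = naive_conv_block(core, m.b1)
    y2 = naive_conv_block(naive_conv_block(core, m.b2a), m.b2b)
    y3 = naive_conv_block(naive_conv_block(naive_conv_block(core, m.b3a), m.b3b), m.b3c)
    y4 = naive_conv_block(naive_maxpool2d(core, 3, 1, 1), m.b4)
    return np.concatenate([core, y1, y2, y3, y4], axis=0)


def naive_dwt(x):
    """(C,H,W) -> four (C,H/2,W/2) bands, orthonormal Haar, explicit loops."""
    C, H, W = x.shape
    ll = np.zeros((C, H // 2, W // 2))
    lh, hl, hh = np.zeros_like(ll), np.zeros_like(ll), np.zeros_like(ll)
    for c in range(C):
        for i in range(H // 2):
            for j in range(W // 2):
                a, b = x[c, 2 * i, 2 * j], x[c, 2 * i, 2 * j + 1]
                cc, d = x[c, 2 * i + 1, 2 * j], x[c, 2 * i + 1, 2 * j + 1]
                ll[c, i, j] = (a + b + cc + d) / 2
                lh[c, i, j] = (a - b + cc - d) / 2
                hl[c, i, j] = (a + b - cc - d) / 2
                hh[c, i, j] = (a - b - cc + d) / 2
    return ll, lh, hl, hh


def naive_idwt(ll, lh, hl, hh):
    C, H, W = ll.shape
    out = np.zeros((C, 2 * H, 2 * W))
    for c in range(C):
        for i in range(H):
            for j in range(W):
                out[c, 2 * i, 2 * j] = (ll[c, i, j] + lh[c, i, j] + hl[c, i, j] + hh[c, i, j]) / 2
                out[c, 2 * i, 2 * j + 1] = (ll[c, i, j] - lh[c, i, j] + hl[c, i, j] - hh[c, i, j]) / 2
                out[c, 2 * i + 1, 2 * j] = (ll[c, i, j] + lh[c, i, j] - hl[c, i, j] - hh[c, i, j]) / 2
                out[c, 2 * i + 1, 2 * j + 1] = (ll[c, i, j] - lh[c, i, j] - hl[c, i, j] + hh[c, i, j]) / 2
    return out


def naive_wtconv(x, module):
    """Literal wavelet-convolution cascade from the module's parameters."""
    cfg = module.cfg
    c, k = cfg.channels, cfg.kernel_size
    pad = k // 2
    lls, highs = [], []
    cur = x.astype(np.float64)
    for lvl in range(cfg.num_levels):
        bands = naive_dwt(cur)
        packed = np.concatenate(bands, axis=0)
        kern = getattr(module, f"level{lvl}_kernel").data.astype(np.float64)
        scale = getattr(module, f"level{lvl}_scale").data.astype(np.float64)
        conved = naive_conv2d(packed, kern, 1, pad, groups=4 * c)
        conved *= scale[:, None, None]
        lls.append(conved[:c])
        highs.append(conved[c:])
        cur = bands[0]
    acc = None
    for lvl in reversed(range(cfg.num_levels)):
        ll = lls[lvl] if acc is None else lls[lvl] + acc
        h = highs[lvl]
        acc = naive_idwt(ll, h[:c], h[c : 2 * c], h[2 * c :])
    if cfg.include_base_path:
        base = naive_conv2d(x.astype(np.float64), module.base_kernel.data.astype(np.float64),
                            1, pad, groups=c)
        base *= module.base_scale.data.astype(np.float64)[:, None, None]
        acc = acc + base
    return acc
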