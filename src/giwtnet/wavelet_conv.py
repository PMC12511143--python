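"""2-D Haar wavelet analysis/synthesis and the wavelet-transform convolution.

The orthonormal Haar convention is used: 1-D analysis filters (1/sqrt(2))(1, 1)
and (1/sqrt(2))(1, -1), applied separably with stride 2.  For a 2x2 block
((a, b), (c, d)) the four subbands are

    LL = (a+b+c+d)/2    LH = (a-b+c-d)/2
    HL = (a+b-c-d)/2    HH = (a-b-c+d)/2

so a constant input of value v transforms to LL = 2v and zero detail bands,
and the transform conserves energy exactly.  Because the filter bank is
orthogonal the synthesis transform is the adjoint of the analysis transform,
which keeps perfect reconstruction and the autograd backward pass trivial.

``WTConv`` is the cascade operator built from this transform: an optional
depthwise convolution at full resolution, plus per-level depthwise
convolutions applied jointly to the four frequency bands of successively
deeper low-frequency maps, recomposed by inverse transforms.  Each level
halves resolution, so a k x k kernel at level L spans 2^L (k-1) + 1 input
pixels — the receptive field grows exponentially while parameters grow only
linearly per level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Module, Parameter, _kaiming_uniform

__all__ = [
    "WTConvConfig",
    "haar_dwt2",
    "haar_idwt2",
    "WTConv",
    "wtconv_forward",
    "wtconv_param_count",
    "wtconv_receptive_field",
]


@dataclass(frozen=True)
class WTConvConfig:
    """Configuration of the wavelet-convolution operator.

    channels: input = output channel count (operator is depthwise).
    kernel_size: odd side of every depthwise kernel.
    num_levels: wavelet decomposition depth L >= 1.
    include_base_path: depthwise conv at full resolution added to the output.
    """

    channels: int
    kernel_size: int = 5
    num_levels: int = 1
    include_base_path: bool = True

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError(f"channels must be >= 1, got {self.channels}")
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd and positive, got {self.kernel_size}")
        if self.num_levels < 1:
            raise ValueError(f"num_levels must be >= 1, got {self.num_levels}")


# ---------------------------------------------------------------------------
# transform cores (plain NumPy; reused by forward and backward)
# ---------------------------------------------------------------------------

def _dwt_core(x: np.ndarray):
    a = x[..., 0::2, 0::2]
    b = x[..., 0::2, 1::2]
    c = x[..., 1::2, 0::2]
    d = x[..., 1::2, 1::2]
    ll = (a + b + c + d) * 0.5
    lh = (a - b + c - d) * 0.5
    hl = (a + b - c - d) * 0.5
    hh = (a - b - c + d) * 0.5
    return ll, lh, hl, hh


def _idwt_core(ll, lh, hl, hh):
    shape = list(ll.shape)
    shape[-2] *= 2
    shape[-1] *= 2
    out = np.empty(shape, dtype=np.float32)
    out[..., 0::2, 0::2] = (ll + lh + hl + hh) * 0.5
    out[..., 0::2, 1::2] = (ll - lh + hl - hh) * 0.5
    out[..., 1::2, 0::2] = (ll + lh - hl - hh) * 0.5
    out[..., 1::2, 1::2] = (ll - lh - hl + hh) * 0.5
    return out


def _validate_spatial(x: np.ndarray) -> None:
    if x.ndim < 2 or x.shape[-1] <= 0 or x.shape[-2] <= 0 or x.size == 0:
        raise ValueError(f"input must be a non-empty array with 2 spatial axes, got shape {x.shape}")


def haar_dwt2(x):
    """Single-level orthonormal 2-D Haar analysis of the two trailing axes.

    Odd-sized inputs are edge-replicated to even size first.  Returns the
    (LL, LH, HL, HH) subbands, each at half (ceil) resolution.
    """
    arr = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float32)
    _validate_spatial(arr)
    pads = [(0, 0)] * (arr.ndim - 2) + [(0, arr.shape[-2] % 2), (0, arr.shape[-1] % 2)]
    if arr.shape[-2] % 2 or arr.shape[-1] % 2:
        arr = np.pad(arr, pads, mode="edge")
    return _dwt_core(arr)


def haar_idwt2(ll, lh, hl, hh):
    """Exact inverse of :func:`haar_dwt2` (for even-sized originals)."""
    bands = [np.asarray(b, dtype=np.float32) for b in (ll, lh, hl, hh)]
    shapes = {b.shape for b in bands}
    if len(shapes) != 1:
        raise ValueError(f"subband shapes differ: {sorted(shapes)}")
    _validate_spatial(bands[0])
    return _idwt_core(*bands)


# ---------------------------------------------------------------------------
# autograd-aware packed transforms (bands packed along the channel axis)
# ---------------------------------------------------------------------------

def dwt_packed(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, 4C, H/2, W/2) with band order [LL, LH, HL, HH]."""
    ll, lh, hl, hh = _dwt_core(x.data)
    out = np.concatenate([ll, lh, hl, hh], axis=1)

    def backward(g):
        if x.requires_grad:
            C = x.data.shape[1]
            x._accum(_idwt_core(g[:, :C], g[:, C : 2 * C], g[:, 2 * C : 3 * C], g[:, 3 * C :]))

    return Tensor._make(out, (x,), backward)


def idwt_packed(x: Tensor) -> Tensor:
    """(N, 4C, H, W) -> (N, C, 2H, 2W); adjoint/inverse of :func:`dwt_packed`."""
    C = x.data.shape[1] // 4
    out = _idwt_core(x.data[:, :C], x.data[:, C : 2 * C], x.data[:, 2 * C : 3 * C], x.data[:, 3 * C :])

    def backward(g):
        if x.requires_grad:
            x._accum(np.concatenate(_dwt_core(g), axis=1))

    return Tensor._make(out, (x,), backward)


# ---------------------------------------------------------------------------
# WTConv
# ---------------------------------------------------------------------------

class WTConv(Module):
    """Depthwise wavelet-transform convolution (stride 1, channels preserved).

    Learnables: one bias-free depthwise k x k kernel plus one scalar scale per
    channel for the base path, and per level one depthwise kernel + scale over
    the 4C packed band channels.  Scales start at 1, kernels fan-in uniform.
    """

    def __init__(self, cfg: WTConvConfig, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        c, k = cfg.channels, cfg.kernel_size
        if cfg.include_base_path:
            self.base_kernel = Parameter(_kaiming_uniform(rng, (c, 1, k, k), k * k))
            self.base_scale = Parameter(np.ones(c, dtype=np.float32))
        for i in range(cfg.num_levels):
            setattr(self, f"level{i}_kernel",
                    Parameter(_kaiming_uniform(rng, (4 * c, 1, k, k), k * k)))
            setattr(self, f"level{i}_scale", Parameter(np.ones(4 * c, dtype=np.float32)))

    def _level(self, i: int):
        return getattr(self, f"level{i}_kernel"), getattr(self, f"level{i}_scale")

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        if x.data.ndim != 4 or x.data.shape[1] != cfg.channels:
            raise ValueError(
                f"expected (N, {cfg.channels}, H, W) input, got shape {x.data.shape}"
            )
        c, k = cfg.channels, cfg.kernel_size
        pad = k // 2

        ll_conved: list[Tensor] = []
        high_conved: list[Tensor] = []
        crops: list[tuple[int, int]] = []
        cur = x
        for i in range(cfg.num_levels):
            H, W = cur.data.shape[-2:]
            if H % 2 or W % 2:
                cur = ag.pad_replicate2d(cur, (0, H % 2, 0, W % 2))
            crops.append((H, W))
            packed = dwt_packed(cur)
            kern, scale = self._level(i)
            conved = ag.conv2d(packed, kern, stride=1, padding=pad, groups=4 * c)
            conved = conved * scale.reshape(1, 4 * c, 1, 1)
            ll_conved.append(conved[:, :c])
            high_conved.append(conved[:, c:])
            cur = packed[:, :c]  # raw low-frequency map feeds the next level

        recomposed = None
        for i in reversed(range(cfg.num_levels)):
            ll = ll_conved[i] if recomposed is None else ll_conved[i] + recomposed
            recomposed = idwt_packed(ag.concat([ll, high_conved[i]], axis=1))
            H, W = crops[i]
            if recomposed.data.shape[-2] != H or recomposed.data.shape[-1] != W:
                recomposed = recomposed[:, :, :H, :W]

        if cfg.include_base_path:
            base = ag.conv2d(x, self.base_kernel, stride=1, padding=pad, groups=c)
            base = base * self.base_scale.reshape(1, c, 1, 1)
            return base + recomposed
        return recomposed


def wtconv_forward(x, wtconv_or_cfg, rng: np.random.Generator | None = None):
    """Functional wrapper: run a :class:`WTConv` (built on the fly from a
    config if needed) on ``x`` and return a NumPy array or Tensor matching the
    input type."""
    module = (
        wtconv_or_cfg
        if isinstance(wtconv_or_cfg, WTConv)
        else WTConv(wtconv_or_cfg, rng=rng)
    )
    if isinstance(x, Tensor):
        return module(x)
    with ag.no_grad():
        return module(Tensor(np.asarray(x, dtype=np.float32))).data


def wtconv_param_count(cfg: WTConvConfig) -> int:
    """Exact learnable-parameter total: depthwise kernels are bias-free and
    each path carries one scalar scale per channel."""
    c, k = cfg.channels, cfg.kernel_size
    total = cfg.num_levels * (4 * c * k * k + 4 * c)
    if cfg.include_base_path:
        total += c * k * k + c
    return total


def wtconv_receptive_field(cfg_or_levels, kernel_size: int | None = None) -> int:
    """1-D span of input pixels influencing one output pixel through the
    deepest wavelet path: 2^L (k - 1) + 1.  ``L = 0`` degenerates to a plain
    depthwise convolution of span k."""
    if isinstance(cfg_or_levels, WTConvConfig):
        L, k = cfg_or_levels.num_levels, cfg_or_levels.kernel_size
    else:
        L, k = int(cfg_or_levels), int(kernel_size)
    if L < 0:
        raise ValueError("num_levels must be >= 0")
    return (2**L) * (k - 1) + 1
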