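"""Ghost-Inception downsampling convolution (GIConv) and its analytic cost model.

GIConv halves the output width through a primary k x k strided convolution
(the "core" feature map, n/2 channels) and recovers the other half through a
four-branch multi-scale mixer applied to the core map:

    branch 1:  1x1 conv            c -> c/4
    branch 2:  1x1 then 3x3        c -> c/8 -> c/4
    branch 3:  1x1, 3x3, 3x3       c -> c/8 -> c/4 -> c/4
    branch 4:  3x3 max-pool (s1, p1) then 1x1   c -> c/4

with c = n/2.  Per output pixel the branches cost (1/4, 13/32, 31/32, 1/4)
c^2 multiply–accumulates, totalling (15/8) c^2, so the full module costs

    H·W·(n/2)·k^2·c_in  +  (15/8)·H·W·(n/2)^2

against H·W·n·k^2·c_in for a standard convolution — a ratio of

    S = 1/2 + 15 n / (32 k^2 c_in),

approximately 0.6 at k = 3, n = 2 c_in.  All convolutions are bias-free with
per-channel normalisation and SiLU; the Inception-internal convolutions are
stride 1 (the primary conv carries the stride).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Conv, MaxPool2d, Module

__all__ = [
    "GIConvConfig",
    "CostReport",
    "InceptionMixer",
    "GIConv",
    "inception_forward",
    "giconv_forward",
    "inception_cost",
    "giconv_cost",
    "cost_ratio",
]


@dataclass(frozen=True)
class GIConvConfig:
    in_channels: int
    out_channels: int
    kernel_size: int = 3
    stride: int = 2

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1 or self.stride < 1:
            raise ValueError("channel counts and stride must be positive")
        if self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd, got {self.kernel_size}")
        if self.out_channels % 8:
            raise ValueError(
                f"out_channels must be divisible by 8 so the n/2 * (1/4, 1/8, 1/4) "
                f"branch widths are integral, got {self.out_channels}"
            )


@dataclass
class CostReport:
    """Multiply–accumulate and parameter accounting for one layer.

    ``macs_total = macs_primary + sum(branches)``; ``ratio_S`` is populated
    when a standard-convolution reference exists for the same configuration.
    """

    macs_primary: int
    macs_branch1: int
    macs_branch2: int
    macs_branch3: int
    macs_branch4: int
    spatial: tuple[int, int]
    channels: int
    params_total: int | None = None
    macs_standard: int | None = None
    macs_total: int = field(init=False)
    ratio_S: float | None = field(init=False, default=None)

    def __post_init__(self):
        self.macs_total = (
            self.macs_primary
            + self.macs_branch1
            + self.macs_branch2
            + self.macs_branch3
            + self.macs_branch4
        )
        if self.macs_standard:
            self.ratio_S = self.macs_total / self.macs_standard

    def to_dict(self) -> dict:
        d = asdict(self)
        d["macs_total"] = self.macs_total
        d["ratio_S"] = self.ratio_S
        return d


class InceptionMixer(Module):
    """The four-branch multi-scale block; channels in = channels out = c."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        if channels % 8:
            raise ValueError(f"channels must be divisible by 8, got {channels}")
        c = channels
        rng = rng or np.random.default_rng(0)
        self.b1 = Conv(c, c // 4, 1, rng=rng)
        self.b2a = Conv(c, c // 8, 1, rng=rng)
        self.b2b = Conv(c // 8, c // 4, 3, rng=rng)
        self.b3a = Conv(c, c // 8, 1, rng=rng)
        self.b3b = Conv(c // 8, c // 4, 3, rng=rng)
        self.b3c = Conv(c // 4, c // 4, 3, rng=rng)
        self.pool = MaxPool2d(3, stride=1, padding=1)
        self.b4 = Conv(c, c // 4, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y1 = self.b1(x)
        y2 = self.b2b(self.b2a(x))
        y3 = self.b3c(self.b3b(self.b3a(x)))
        y4 = self.b4(self.pool(x))
        return ag.concat([y1, y2, y3, y4], axis=1)


class GIConv(Module):
    """Primary strided conv to n/2 channels, Inception mixer, concat to n."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = GIConvConfig(c_in, c_out, k, stride)
        rng = rng or np.random.default_rng(0)
        self.primary = Conv(c_in, c_out // 2, k, stride, rng=rng)
        self.mixer = InceptionMixer(c_out // 2, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.data.shape[1]}"
            )
        core = self.primary(x)
        return ag.concat([core, self.mixer(core)], axis=1)


def inception_forward(x, channels: int | None = None,
                      rng: np.random.Generator | None = None):
    """Functional mixer forward; accepts a NumPy array or Tensor."""
    arr = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    c = channels or arr.data.shape[1]
    mixer = InceptionMixer(c, rng=rng)
    with ag.no_grad():
        out = mixer(arr)
    return out if isinstance(x, Tensor) else out.data


def giconv_forward(x, cfg: GIConvConfig, rng: np.random.Generator | None = None):
    """Functional GIConv forward; accepts a NumPy array or Tensor."""
    arr = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    module = GIConv(cfg.in_channels, cfg.out_channels, cfg.kernel_size, cfg.stride, rng=rng)
    with ag.no_grad():
        out = module(arr)
    return out if isinstance(x, Tensor) else out.data


def inception_cost(H: int, w: int, c: int) -> CostReport:
    """Analytic per-branch MACs of the mixer at spatial size H x w, c channels.

    Branches cost (1/4, 13/32, 31/32, 1/4)·H·w·c^2; the totals are integers
    whenever c is divisible by 8.  Pooling contributes no MACs.
    """
    if H < 1 or w < 1 or c < 1:
        raise ValueError("H, w, c must be positive")
    hw = H * w
    b1 = hw * c * (c // 4) if c % 4 == 0 else hw * c * c // 4
    b2 = hw * (c * (c // 8) + 9 * (c // 8) * (c // 4)) if c % 8 == 0 else int(hw * 13 * c * c / 32)
    b3 = (
        hw * (c * (c // 8) + 9 * (c // 8) * (c // 4) + 9 * (c // 4) * (c // 4))
        if c % 8 == 0
        else int(hw * 31 * c * c / 32)
    )
    b4 = b1
    return CostReport(0, b1, b2, b3, b4, spatial=(H, w), channels=c)


def giconv_cost(cfg: GIConvConfig, out_H: int, out_W: int) -> CostReport:
    """Analytic GIConv MACs at the given *output* resolution, with the
    standard-convolution reference (same k, stride, channels) and ratio S."""
    n, c_in, k = cfg.out_channels, cfg.in_channels, cfg.kernel_size
    primary = out_H * out_W * (n // 2) * k * k * c_in
    mix = inception_cost(out_H, out_W, n // 2)
    standard = out_H * out_W * n * k * k * c_in
    report = CostReport(
        primary,
        mix.macs_branch1,
        mix.macs_branch2,
        mix.macs_branch3,
        mix.macs_branch4,
        spatial=(out_H, out_W),
        channels=n // 2,
        params_total=GIConv(c_in, n, k, cfg.stride).param_count(),
        macs_standard=standard,
    )
    return report


def cost_ratio(k: int, n: int, c: int) -> float:
    """Closed-form GIConv/standard-conv computation ratio: 1/2 + 15n/(32 k^2 c)."""
    if k < 1 or n < 1 or c < 1:
        raise ValueError("k, n, c must be positive")
    return 0.5 + 15.0 * n / (32.0 * k * k * c)
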