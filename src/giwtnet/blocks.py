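"""Building blocks of the detector beyond GIConv and the wavelet convolution.

Baseline-inherited pieces (Bottleneck, C3k/C3k2, SPPF, C2PSA, anchor-free
head) follow the YOLOv11-small conventions: width multiplier 0.5, depth
multiplier 0.5 (stage repeats 1, two bottlenecks inside C3k), expansion 0.25
for the first two backbone stages and 0.5 elsewhere.  The wavelet variants
(Bottleneck_WT / C3K_WT / C3K2_WT) replace both 3x3 convolutions of the
bottleneck with wavelet convolutions followed by per-channel normalisation
and SiLU; a second-conv-only variant is kept for calibration sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import BatchNorm2d, Conv, Conv2d, Linear, MaxPool2d, Module, Sequential
from .wavelet_conv import WTConv, WTConvConfig

__all__ = [
    "BlockSpec",
    "SEConfig",
    "SqueezeExcite",
    "se_forward",
    "Bottleneck",
    "BottleneckWT",
    "C3k",
    "C3kWT",
    "C3k2",
    "C3K2_WT",
    "SPPF",
    "Attention",
    "PSABlock",
    "C2PSA",
    "Detect",
    "detect_forward",
    "calibrate_wtconv_config",
]

_BLOCK_KINDS = {
    "conv", "giconv", "c3k2", "c3k2_wt", "sppf", "c2psa", "se",
    "upsample", "concat", "detect",
}


@dataclass(frozen=True)
class BlockSpec:
    """One layer description in a network plan (mirrors the model config)."""

    kind: str
    in_channels: int = 0
    out_channels: int = 0
    repeats: int = 1
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}; allowed: {sorted(_BLOCK_KINDS)}")
        e = self.flags.get("e")
        if e is not None and e not in (0.25, 0.5):
            raise ValueError(f"expansion must be 0.25 or 0.5, got {e}")


@dataclass(frozen=True)
class SEConfig:
    channels: int
    reduction: int = 16

    def __post_init__(self):
        if self.channels % self.reduction or self.channels // self.reduction < 1:
            raise ValueError(
                f"reduction {self.reduction} must divide channels {self.channels}"
            )


class SqueezeExcite(Module):
    """Squeeze-and-excitation channel gate: global average pool, bottlenecked
    two-layer excitation (SiLU then sigmoid), per-channel rescale."""

    def __init__(self, cfg: SEConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        rng = rng or np.random.default_rng(0)
        self.fc1 = Linear(cfg.channels, cfg.channels // cfg.reduction, rng=rng)
        self.fc2 = Linear(cfg.channels // cfg.reduction, cfg.channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.cfg.channels:
            raise ValueError(
                f"expected {self.cfg.channels} channels, got {x.data.shape[1]}"
            )
        squeezed = x.mean(axis=(2, 3))  # (N, C)
        gate = self.fc2(self.fc1(squeezed).silu()).sigmoid()
        return x * gate.reshape(x.data.shape[0], x.data.shape[1], 1, 1)


def se_forward(x, cfg: SEConfig, rng: np.random.Generator | None = None):
    module = SqueezeExcite(cfg, rng=rng)
    if isinstance(x, Tensor):
        return module(x)
    with ag.no_grad():
        return module(Tensor(np.asarray(x, dtype=np.float32))).data


class Bottleneck(Module):
    def __init__(self, c1: int, c2: int, shortcut: bool = True,
                 k: tuple[int, int] = (3, 3), e: float = 1.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, k[0], rng=rng)
        self.cv2 = Conv(c_, c2, k[1], rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class _WTConvBlock(Module):
    """WTConv + per-channel normalisation + SiLU (the drop-in for a 3x3 Conv)."""

    def __init__(self, channels: int, wt_cfg: WTConvConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if wt_cfg.channels != channels:
            wt_cfg = WTConvConfig(channels, wt_cfg.kernel_size, wt_cfg.num_levels,
                                  wt_cfg.include_base_path)
        self.wt = WTConv(wt_cfg, rng=rng)
        self.bn = BatchNorm2d(channels)

    def forward(self, x):
        return self.bn(self.wt(x)).silu()


class BottleneckWT(Module):
    """Residual bottleneck whose convolutions are wavelet convolutions.

    ``replace='both'`` (default) swaps both 3x3 convolutions; ``'second'``
    keeps the first as a standard Conv — retained for calibration sweeps.
    """

    def __init__(self, channels: int, wt_cfg: WTConvConfig | None = None,
                 shortcut: bool = True, replace: str = "both",
                 rng: np.random.Generator | None = None):
        super().__init__()
        wt_cfg = wt_cfg or WTConvConfig(channels)
        if replace not in ("both", "second"):
            raise ValueError(f"replace must be 'both' or 'second', got {replace!r}")
        if replace == "both":
            self.cv1 = _WTConvBlock(channels, wt_cfg, rng=rng)
        else:
            self.cv1 = Conv(channels, channels, 3, rng=rng)
        self.cv2 = _WTConvBlock(channels, wt_cfg, rng=rng)
        self.add = shortcut

    def forward(self, x):
        if x.data.shape[1] != self.cv2.bn.gamma.data.size:
            raise ValueError(
                f"expected {self.cv2.bn.gamma.data.size} channels, got {x.data.shape[1]}"
            )
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3k(Module):
    def __init__(self, c1: int, c2: int, n: int = 2, shortcut: bool = True,
                 e: float = 0.5, rng: np.random.Generator | None = None):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1, rng=rng)
        self.cv2 = Conv(c1, c_, 1, rng=rng)
        self.cv3 = Conv(2 * c_, c2, 1, rng=rng)
        self.m = Sequential(*[
            Bottleneck(c_, c_, shortcut, k=(3, 3), e=1.0, rng=rng) for _ in range(n)
        ])

    def forward(self, x):
        return self.cv3(ag.concat([self.m(self.cv1(x)), self.cv2(x)], axis=1))


class C3kWT(C3k):
    """C3k whose inner bottlenecks are wavelet bottlenecks."""

    def __init__(self, c1: int, c2: int, n: int = 2, shortcut: bool = True,
                 e: float = 0.5, wt_cfg: WTConvConfig | None = None,
                 replace: str = "both", rng: np.random.Generator | None = None):
        super().__init__(c1, c2, n, shortcut, e, rng=rng)
        c_ = int(c2 * e)
        self.m = Sequential(*[
            BottleneckWT(c_, wt_cfg, shortcut, replace, rng=rng) for _ in range(n)
        ])


class C3k2(Module):
    """Split/transform/concat stage.  With ``wt_cfg`` set this is the wavelet
    variant C3K2_WT: inner units are BottleneckWT (c3k False) or C3kWT (True).
    """

    def __init__(self, c1: int, c2: int, n: int = 1, c3k: bool = False,
                 e: float = 0.5, shortcut: bool = True,
                 wt_cfg: WTConvConfig | None = None, replace: str = "both",
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.c = int(c2 * e)
        if self.c < 1:
            raise ValueError(f"expansion {e} of {c2} channels leaves no hidden width")
        self.cv1 = Conv(c1, 2 * self.c, 1, rng=rng)
        self.cv2 = Conv((2 + n) * self.c, c2, 1, rng=rng)
        units = []
        for _ in range(n):
            if wt_cfg is None:
                unit = (C3k(self.c, self.c, 2, shortcut, rng=rng) if c3k
                        else Bottleneck(self.c, self.c, shortcut, k=(3, 3), e=1.0, rng=rng))
            else:
                unit = (C3kWT(self.c, self.c, 2, shortcut, wt_cfg=wt_cfg, replace=replace, rng=rng)
                        if c3k
                        else BottleneckWT(self.c, wt_cfg, shortcut, replace, rng=rng))
            units.append(unit)
        self.units = units
        for i, u in enumerate(units):
            setattr(self, f"unit{i}", u)

    def forward(self, x):
        y = self.cv1(x)
        parts = [y[:, : self.c], y[:, self.c :]]
        for unit in self.units:
            parts.append(unit(parts[-1]))
        return self.cv2(ag.concat(parts, axis=1))


def C3K2_WT(c1: int, c2: int, n: int = 1, c3k: bool = False, e: float = 0.5,
            wt_cfg: WTConvConfig | None = None, replace: str = "both",
            rng: np.random.Generator | None = None) -> C3k2:
    """Constructor for the wavelet C3k2 variant (defaults k=5, 1 level)."""
    return C3k2(c1, c2, n, c3k, e, True, wt_cfg or WTConvConfig(max(int(c2 * e), 1)),
                replace, rng=rng)


class SPPF(Module):
    """Spatial pyramid pooling (fast): chained 5x5 max-pools emulate 5/9/13
    windows, concatenated and fused."""

    def __init__(self, c1: int, c2: int, k: int = 5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = Conv(c1, c_, 1, rng=rng)
        self.pool = MaxPool2d(k, stride=1, padding=k // 2)
        self.cv2 = Conv(4 * c_, c2, 1, rng=rng)

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(self.pool(y[-1]))
        return self.cv2(ag.concat(y, axis=1))


class Attention(Module):
    """Multi-head self-attention over spatial positions with a depthwise
    positional-encoding branch (baseline C2PSA convention)."""

    def __init__(self, dim: int, num_heads: int = 8, attn_ratio: float = 0.5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.key_dim = int(self.head_dim * attn_ratio)
        self.scale = self.key_dim**-0.5
        nh_kd = self.key_dim * num_heads
        h = dim + nh_kd * 2
        self.qkv = Conv(dim, h, 1, act=False, rng=rng)
        self.proj = Conv(dim, dim, 1, act=False, rng=rng)
        self.pe = Conv(dim, dim, 3, groups=dim, act=False, rng=rng)

    def forward(self, x):
        B, C, H, W = x.data.shape
        N = H * W
        qkv = self.qkv(x).reshape(B, self.num_heads, self.key_dim * 2 + self.head_dim, N)
        q = qkv[:, :, : self.key_dim]
        k = qkv[:, :, self.key_dim : 2 * self.key_dim]
        v = qkv[:, :, 2 * self.key_dim :]
        attn = (q.transpose(0, 1, 3, 2) @ k) * self.scale
        attn = attn.softmax(axis=-1)
        out = (v @ attn.transpose(0, 1, 3, 2)).reshape(B, C, H, W)
        out = out + self.pe(v.reshape(B, C, H, W))
        return self.proj(out)


class PSABlock(Module):
    def __init__(self, c: int, attn_ratio: float = 0.5, num_heads: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.attn = Attention(c, num_heads, attn_ratio, rng=rng)
        self.ffn = Sequential(Conv(c, c * 2, 1, rng=rng), Conv(c * 2, c, 1, act=False, rng=rng))

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.ffn(x)


class C2PSA(Module):
    """Partial self-attention stage: half the channels pass through attention
    blocks, the other half skip; fused by 1x1 convolutions."""

    def __init__(self, c1: int, c2: int, n: int = 1, e: float = 0.5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.c = int(c1 * e)
        self.cv1 = Conv(c1, 2 * self.c, 1, rng=rng)
        self.cv2 = Conv(2 * self.c, c2, 1, rng=rng)
        self.m = Sequential(*[
            PSABlock(self.c, 0.5, max(self.c // 64, 1), rng=rng) for _ in range(n)
        ])

    def forward(self, x):
        y = self.cv1(x)
        a, b = y[:, : self.c], y[:, self.c :]
        return self.cv2(ag.concat([a, self.m(b)], axis=1))


class Detect(Module):
    """Anchor-free detection head over three scales (strides 8/16/32).

    Per cell it predicts class logits and four side distances in
    distribution-focal form (``reg_max`` bins per side, in stride units).
    """

    def __init__(self, nc: int, channels: tuple[int, int, int],
                 reg_max: int = 16, strides: tuple[int, int, int] = (8, 16, 32),
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.nc = nc
        self.reg_max = reg_max
        self.strides = tuple(strides)
        c2 = max(16, channels[0] // 4, 4 * reg_max)
        c3 = max(channels[0], min(nc, 100))
        prior_logit = float(np.log(0.01 / 0.99))  # start with ~1% objectness
        for i, ch in enumerate(channels):
            box = Sequential(
                Conv(ch, c2, 3, rng=rng), Conv(c2, c2, 3, rng=rng),
                Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng),
            )
            cls = Sequential(
                Conv(ch, c3, 3, rng=rng), Conv(c3, c3, 3, rng=rng),
                Conv2d(c3, nc, 1, bias=True, rng=rng),
            )
            cls.layers[-1].bias.data[:] = prior_logit
            setattr(self, f"box{i}", box)
            setattr(self, f"cls{i}", cls)

    def forward(self, features: list[Tensor]) -> list[tuple[Tensor, Tensor]]:
        if len(features) != len(self.strides):
            raise ValueError(
                f"expected {len(self.strides)} feature maps, got {len(features)}"
            )
        out = []
        for i, f in enumerate(features):
            out.append((getattr(self, f"box{i}")(f), getattr(self, f"cls{i}")(f)))
        return out

    # -- decoding (plain NumPy; used at inference) -------------------------
    def decode_scale(self, box_logits: np.ndarray, cls_logits: np.ndarray,
                     stride: int) -> tuple[np.ndarray, np.ndarray]:
        """Decode one scale: returns (boxes (N,HW,4) xyxy pixels,
        scores (N,HW,nc) in (0,1))."""
        N, _, H, W = box_logits.shape
        d = box_logits.reshape(N, 4, self.reg_max, H, W)
        d = d - d.max(axis=2, keepdims=True)
        p = np.exp(d)
        p /= p.sum(axis=2, keepdims=True)
        dist = (p * np.arange(self.reg_max, dtype=np.float32)[None, None, :, None, None]).sum(axis=2)
        jj, ii = np.meshgrid(np.arange(W), np.arange(H))
        cx = (jj + 0.5) * stride
        cy = (ii + 0.5) * stride
        x1 = cx[None] - dist[:, 0] * stride
        y1 = cy[None] - dist[:, 1] * stride
        x2 = cx[None] + dist[:, 2] * stride
        y2 = cy[None] + dist[:, 3] * stride
        boxes = np.stack([x1, y1, x2, y2], axis=-1).reshape(N, H * W, 4)
        with np.errstate(over="ignore"):
            scores = 1.0 / (1.0 + np.exp(-cls_logits))
        scores = scores.transpose(0, 2, 3, 1).reshape(N, H * W, self.nc)
        return boxes, scores


def detect_forward(features, nc: int = 6, rng: np.random.Generator | None = None):
    """Functional head forward on three feature maps (NumPy arrays ok)."""
    feats = [f if isinstance(f, Tensor) else Tensor(np.asarray(f, dtype=np.float32))
             for f in features]
    head = Detect(nc, tuple(f.data.shape[1] for f in feats), rng=rng)
    with ag.no_grad():
        return head(feats)


# ---------------------------------------------------------------------------
# calibration of the wavelet-convolution configuration against printed counts
# ---------------------------------------------------------------------------

_C3K2_WT_STAGES = (
    # (c1, c2, e, c3k) of the four backbone stages at width 0.5
    (64, 128, 0.25, False),
    (128, 256, 0.25, False),
    (256, 256, 0.5, True),
    (512, 512, 0.5, True),
)


def calibrate_wtconv_config(targets: list[int] | None = None) -> dict:
    """Enumerate wavelet-convolution candidates and report each candidate's
    four C3K2_WT stage parameter counts beside the target counts.

    The printed stage counts cannot be reproduced from any configuration the
    source describes, so this reports deviations and flags the closest
    candidate — it never adopts a "match".
    """
    targets = list(targets) if targets is not None else [26080, 103360, 293632, 1127936]
    rows = []
    baseline = [
        C3k2(c1, c2, 1, c3k, e).param_count() for c1, c2, e, c3k in _C3K2_WT_STAGES
    ]
    rows.append({
        "candidate": "baseline (no wavelet conv)",
        "kernel": None, "levels": None, "replace": None, "scales": None,
        "stage_counts": baseline,
        "abs_deviation": [abs(b - t) for b, t in zip(baseline, targets)],
    })
    best = None
    for k in (3, 5, 7):
        for L in (1, 2, 3):
            for replace in ("both", "second"):
                for scales in (True, False):
                    counts = []
                    for c1, c2, e, c3k in _C3K2_WT_STAGES:
                        cfg = WTConvConfig(max(int(c2 * e), 1), k, L)
                        block = C3K2_WT(c1, c2, 1, c3k, e, wt_cfg=cfg, replace=replace)
                        n = block.param_count()
                        if not scales:  # subtract the per-channel scale parameters
                            for name, p in block.named_parameters():
                                if name.endswith("_scale"):
                                    n -= p.data.size
                        counts.append(n)
                    dev = [abs(c - t) for c, t in zip(counts, targets)]
                    row = {
                        "candidate": f"k={k}, L={L}, replace={replace}, scales={scales}",
                        "kernel": k, "levels": L, "replace": replace, "scales": scales,
                        "stage_counts": counts,
                        "abs_deviation": dev,
                    }
                    rows.append(row)
                    if best is None or sum(dev) < sum(best["abs_deviation"]):
                        best = row
    return {
        "targets": targets,
        "rows": rows,
        "closest_candidate": best["candidate"],
        "note": (
            "no enumerated configuration reproduces the target counts exactly; "
            "the closest candidate is reported, not adopted"
        ),
    }
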