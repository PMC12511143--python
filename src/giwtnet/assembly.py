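"""Assembly of the full detector graph and per-layer cost accounting.

Backbone: stem Conv, four GIConv downsampling stages interleaved with four
wavelet C3k2 stages, SPPF, C2PSA.  Neck: top-down + bottom-up fusion with
upsample/concat and wavelet C3k2 fusion blocks.  Head: one squeeze-excitation
gate per exported scale (P3/P4/P5, strides 8/16/32) placed between neck and
head, then the anchor-free detection head.

The per-layer parameter column of the reference table corresponds to a
320x320 input (spatial sizes 160...10); the training default input is
640x640.  Spatial sizes here are parameterised by input size, so both views
are available.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor, count_macs
from .blocks import C2PSA, C3K2_WT, Detect, SEConfig, SPPF, SqueezeExcite
from .giconv import GIConv
from .nn import Conv, Module, Upsample
from .wavelet_conv import WTConvConfig

__all__ = [
    "NetworkSpec",
    "ModelSummary",
    "GIWTDetector",
    "build_model",
    "summarize",
    "compare_to_reference",
    "relative_reduction",
    "TABLE2_REFERENCE",
    "PINNED_ROWS",
    "save_checkpoint",
    "load_checkpoint",
]

# Printed per-layer parameter counts of the reference architecture table.
TABLE2_REFERENCE: dict[str, int] = {
    "conv_stem": 928,
    "giconv_p2": 11296,
    "c3k2_wt_p2": 26080,
    "giconv_p3": 81728,
    "c3k2_wt_p3": 103360,
    "giconv_p4": 326272,
    "c3k2_wt_p4": 293632,
    "giconv_p5": 713984,
    "c3k2_wt_p5": 1127936,
    "sppf": 656896,
    "c2psa": 990976,
}

# Rows whose construction is fully pinned by derivable conventions.
PINNED_ROWS = ("conv_stem", "giconv_p2", "giconv_p3", "giconv_p4", "giconv_p5", "sppf")


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of the assembled detector.

    ``width_mult`` 0.5 is the reference ("small") scale with backbone widths
    32/64/128/256/512; 0.25 is the fast desk-scale variant.  The wavelet
    kernel/levels are exposed because the source never fixes them.
    """

    width_mult: float = 0.5
    num_classes: int = 6
    giconv_kernel: int = 3
    wtconv_kernel: int = 5
    wtconv_levels: int = 1
    se_reduction: int = 16
    se_placement: str = "neck_head"  # or "backbone"
    reg_max: int = 16

    def __post_init__(self):
        if self.se_placement not in ("neck_head", "backbone"):
            raise ValueError(f"se_placement must be 'neck_head' or 'backbone'")
        if not 0 < self.width_mult <= 1:
            raise ValueError(f"width_mult must be in (0, 1], got {self.width_mult}")

    def channel(self, base: int) -> int:
        """Width-scaled channel count (base values are the width-0.5 plan)."""
        return max(8, int(round(base * self.width_mult / 0.5 / 8)) * 8)

    def wt_cfg(self, channels: int) -> WTConvConfig:
        return WTConvConfig(channels, self.wtconv_kernel, self.wtconv_levels)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**d)


@dataclass
class ModelSummary:
    rows: list[dict]
    total_params: int
    total_gflops: float
    input_size: tuple[int, int]

    def to_dict(self) -> dict:
        return asdict(self)

    def format_table(self) -> str:
        lines = [f"{'layer':<14}{'output':>10}{'params':>12}{'GFLOPs':>10}"]
        for r in self.rows:
            out = "x".join(str(s) for s in r["output_size"])
            lines.append(f"{r['name']:<14}{out:>10}{r['params']:>12}{r['gflops']:>10.3f}")
        lines.append(
            f"{'total':<14}{'':>10}{self.total_params:>12}{self.total_gflops:>10.3f} "
            f"@ {self.input_size[0]}x{self.input_size[1]}"
        )
        return "\n".join(lines)


class GIWTDetector(Module):
    """The assembled detector; forward yields raw (box, cls) logits per scale."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        ch = spec.channel
        c1, c2, c3, c4, c5 = ch(32), ch(64), ch(128), ch(256), ch(512)
        k = spec.giconv_kernel
        wt = spec.wt_cfg
        e_early = 0.25

        def c3k2wt(cin, cout, c3k, e):
            return C3K2_WT(cin, cout, 1, c3k, e, wt_cfg=wt(max(int(cout * e), 8)), rng=rng)

        layers: list[tuple[str, Module | str, object]] = []

        def add(name, module, src=-1):
            layers.append((name, module, src))

        add("conv_stem", Conv(3, c1, 3, 2, rng=rng))
        add("giconv_p2", GIConv(c1, c2, k, 2, rng=rng))
        add("c3k2_wt_p2", c3k2wt(c2, c3, False, e_early))
        add("giconv_p3", GIConv(c3, c3, k, 2, rng=rng))
        add("c3k2_wt_p3", c3k2wt(c3, c4, False, e_early))           # P3 tap
        add("giconv_p4", GIConv(c4, c4, k, 2, rng=rng))
        add("c3k2_wt_p4", c3k2wt(c4, c4, True, 0.5))                # P4 tap
        add("giconv_p5", GIConv(c4, c5, k, 2, rng=rng))
        add("c3k2_wt_p5", c3k2wt(c5, c5, True, 0.5))
        add("sppf", SPPF(c5, c5, rng=rng))
        add("c2psa", C2PSA(c5, c5, 1, rng=rng))                     # P5 tap

        p3_tap, p4_tap, p5_tap = "c3k2_wt_p3", "c3k2_wt_p4", "c2psa"
        if spec.se_placement == "backbone":
            add("se_p3", SqueezeExcite(SEConfig(c4, spec.se_reduction), rng=rng), p3_tap)
            add("se_p4", SqueezeExcite(SEConfig(c4, spec.se_reduction), rng=rng), p4_tap)
            add("se_p5", SqueezeExcite(SEConfig(c5, spec.se_reduction), rng=rng), p5_tap)
            p3_tap, p4_tap, p5_tap = "se_p3", "se_p4", "se_p5"

        add("upsample_1", Upsample(2), p5_tap)
        add("concat_1", "concat", ["upsample_1", p4_tap])
        add("c3k2_wt_n1", c3k2wt(c5 + c4, c4, False, 0.5))
        add("upsample_2", Upsample(2))
        add("concat_2", "concat", ["upsample_2", p3_tap])
        add("c3k2_wt_n2", c3k2wt(c4 + c4, c3, False, 0.5))          # neck P3 out
        add("conv_down1", Conv(c3, c3, 3, 2, rng=rng))
        add("concat_3", "concat", ["conv_down1", "c3k2_wt_n1"])
        add("c3k2_wt_n3", c3k2wt(c3 + c4, c4, False, 0.5))          # neck P4 out
        add("conv_down2", Conv(c4, c4, 3, 2, rng=rng))
        add("concat_4", "concat", ["conv_down2", p5_tap])
        add("c3k2_wt_n4", c3k2wt(c4 + c5, c5, True, 0.5))           # neck P5 out

        out_p3, out_p4, out_p5 = "c3k2_wt_n2", "c3k2_wt_n3", "c3k2_wt_n4"
        if spec.se_placement == "neck_head":
            add("se_p3", SqueezeExcite(SEConfig(c3, spec.se_reduction), rng=rng), out_p3)
            add("se_p4", SqueezeExcite(SEConfig(c4, spec.se_reduction), rng=rng), out_p4)
            add("se_p5", SqueezeExcite(SEConfig(c5, spec.se_reduction), rng=rng), out_p5)
            out_p3, out_p4, out_p5 = "se_p3", "se_p4", "se_p5"

        add("detect", Detect(spec.num_classes, (c3, c4, c5), spec.reg_max, rng=rng),
            [out_p3, out_p4, out_p5])

        self.graph = layers
        self.name_to_idx = {name: i for i, (name, _, _) in enumerate(layers)}
        for name, module, _ in layers:
            if isinstance(module, Module):
                setattr(self, f"layer_{name}", module)
        self.feature_channels = (c3, c4, c5)
        self.strides = (8, 16, 32)

    # -- execution ---------------------------------------------------------
    def _resolve(self, src, outputs: list, idx: int):
        if src == -1:
            return outputs[idx - 1]
        if isinstance(src, str):
            return outputs[self.name_to_idx[src]]
        return [outputs[self.name_to_idx[s]] for s in src]

    def forward(self, x: Tensor, trace: list | None = None):
        if x.data.ndim != 4 or x.data.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got shape {x.data.shape}")
        if x.data.shape[2] % 32 or x.data.shape[3] % 32:
            raise ValueError(
                f"input spatial size {x.data.shape[2:]} must be divisible by 32"
            )
        outputs: list = [None] * len(self.graph)
        for i, (name, module, src) in enumerate(self.graph):
            inp = x if i == 0 else self._resolve(src, outputs, i)
            if module == "concat":
                out = ag.concat(inp, axis=1)
                macs = 0
            else:
                with count_macs() as cm:
                    out = module(inp)
                macs = cm.total
            outputs[i] = out
            if trace is not None:
                if isinstance(out, list):  # detection head: one row, P3 size
                    shape = tuple(out[0][0].data.shape[2:])
                else:
                    shape = tuple(out.data.shape[2:])
                params = module.param_count() if isinstance(module, Module) else 0
                trace.append({"name": name, "output_size": shape,
                              "params": params, "gflops": 2 * macs / 1e9})
        return outputs[-1]

    def layer(self, name: str) -> Module:
        return self.graph[self.name_to_idx[name]][1]


def build_model(spec: NetworkSpec | None = None, seed: int = 0) -> GIWTDetector:
    """Deterministically construct the detector; equal seeds give bit-identical
    parameter vectors."""
    spec = spec or NetworkSpec()
    return GIWTDetector(spec, np.random.default_rng(seed))


def summarize(model: GIWTDetector, input_size: tuple[int, int] = (320, 320)) -> ModelSummary:
    """Per-layer parameter and GFLOP accounting at the stated input size.

    GFLOPs are 2 x counted convolution/linear multiply–accumulates;
    normalisation, activations and pooling are excluded.
    """
    model.eval()
    trace: list[dict] = []
    x = Tensor(np.zeros((1, 3, input_size[0], input_size[1]), dtype=np.float32))
    with ag.no_grad():
        model(x, trace=trace)
    total_params = model.param_count()
    total_gflops = sum(r["gflops"] for r in trace)
    return ModelSummary(trace, total_params, total_gflops, tuple(input_size))


def compare_to_reference(summary: ModelSummary,
                         reference: dict[str, int] | None = None) -> dict:
    """Per-row diff of a summary against a reference layer->parameter table.

    ``all_pinned_match`` is true iff every pinned row (stem, the four GIConv
    stages, SPPF) matches exactly.
    """
    reference = reference if reference is not None else TABLE2_REFERENCE
    by_name = {r["name"]: r for r in summary.rows}
    missing = [k for k in reference if k not in by_name]
    if missing:
        raise ValueError(f"reference rows not present in summary: {missing}")
    rows = []
    for name, expected in reference.items():
        actual = by_name[name]["params"]
        rows.append({
            "name": name,
            "expected": expected,
            "actual": actual,
            "abs_deviation": abs(actual - expected),
            "rel_deviation": abs(actual - expected) / expected if expected else 0.0,
            "match": actual == expected,
            "pinned": name in PINNED_ROWS,
        })
    mismatches = [r for r in rows if not r["match"]]
    return {
        "rows": rows,
        "mismatches": mismatches,
        "all_pinned_match": all(r["match"] for r in rows if r["pinned"]),
    }


def relative_reduction(baseline: float, improved: float) -> float:
    """Percentage reduction 100 (a - b)/a, e.g. of GFLOPs between models."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (baseline - improved) / baseline


# ---------------------------------------------------------------------------
# checkpoints (npz payload with the spec embedded as JSON)
# ---------------------------------------------------------------------------

def save_checkpoint(model: GIWTDetector, path) -> None:
    state = {k.replace(".", "/"): v for k, v in model.state_dict().items()}
    np.savez(path, __spec__=np.frombuffer(
        json.dumps(model.spec.to_dict()).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> GIWTDetector:
    payload = np.load(path)
    spec = NetworkSpec.from_dict(json.loads(bytes(payload["__spec__"]).decode()))
    model = build_model(spec, seed=0)
    state = {k.replace("/", "."): payload[k] for k in payload.files if k != "__spec__"}
    model.load_state_dict(state)
    return model
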