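"""Reverse-mode automatic differentiation over NumPy arrays.

This is the compute core of the package: a small define-by-run tape with the
operations a convolutional detector needs (convolution, pooling, nearest
upsampling, batch statistics, matmul attention, the elementwise zoo) plus a
multiply–accumulate counter used by the analytic cost model's instrumented
cross-checks.

Arrays are float32 throughout.  Gradients are only tracked while
``is_grad_enabled()`` is true and at least one input requires a gradient;
inference therefore builds no graph.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "count_macs",
    "concat",
    "stack",
    "where",
    "maximum",
    "minimum",
]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


# ---------------------------------------------------------------------------
# multiply–accumulate instrumentation
# ---------------------------------------------------------------------------

class MacCounter:
    """Accumulates conv / linear multiply–accumulates during forward passes.

    Normalisation, activations and pooling contribute nothing, matching the
    GFLOPs convention used for detector reporting (2 FLOPs per MAC).
    """

    def __init__(self) -> None:
        self.total = 0

    def add(self, n: int) -> None:
        self.total += int(n)


_MAC_STACK: list[MacCounter] = []


@contextmanager
def count_macs():
    counter = MacCounter()
    _MAC_STACK.append(counter)
    try:
        yield counter
    finally:
        _MAC_STACK.pop()


def _record_macs(n: int) -> None:
    for counter in _MAC_STACK:
        counter.add(n)


# ---------------------------------------------------------------------------
# Tensor
# ---------------------------------------------------------------------------

def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ----------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                buf = np.zeros_like(self.data)
                np.add.at(buf, idx, g)
                self._accum(buf)

        return Tensor._make(np.ascontiguousarray(out_data), (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims=False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            expanded = out_data
            ge = g
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                expanded = np.expand_dims(out_data, axes)
                ge = np.expand_dims(g, axes)
            mask = (self.data == expanded).astype(np.float32)
            mask /= np.maximum(mask.sum(axis=axis, keepdims=True), 1.0)
            self._accum(mask * ge)

        return Tensor._make(out_data, (self,), backward)

    # -- elementwise functions --------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._make(out_data, (self,), backward)

    def atan(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / (1.0 + self.data**2))

        return Tensor._make(np.arctan(self.data), (self,), backward)

    def sigmoid(self):
        with np.errstate(over="ignore"):
            out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def silu(self):
        with np.errstate(over="ignore"):
            sig = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * sig

        def backward(g):
            if self.requires_grad:
                self._accum(g * sig * (1.0 + self.data * (1.0 - sig)))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- linear algebra ----------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)
        _record_macs(out_data.size // out_data.shape[-1] * other.data.shape[-2] * out_data.shape[-1])

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __matmul__ = matmul

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - dot))

        return Tensor._make(out_data, (self,), backward)

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        soft = np.exp(out_data)

        def backward(g):
            if self.requires_grad:
                self._accum(g - soft * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out_data, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# multi-input ops
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(lo), int(hi))
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tensors, backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tensors, backward)


def maximum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    mask = a.data >= b.data
    out_data = np.where(mask, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (~mask), b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def minimum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    mask = a.data <= b.data
    out_data = np.where(mask, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (~mask), b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def where(cond: np.ndarray, a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    cond = np.asarray(cond, dtype=bool)
    out_data = np.where(cond, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * cond, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * (~cond), b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# padding
# ---------------------------------------------------------------------------

def pad_zero2d(x: Tensor, pad: tuple[int, int, int, int]) -> Tensor:
    """Zero-pad the two trailing (spatial) axes: (top, bottom, left, right)."""
    t, b, l, r = pad
    if t == b == l == r == 0:
        return x
    out_data = np.pad(x.data, ((0, 0),) * (x.ndim - 2) + ((t, b), (l, r)))

    def backward(g):
        if x.requires_grad:
            sl = (slice(None),) * (x.ndim - 2) + (
                slice(t, g.shape[-2] - b or None),
                slice(l, g.shape[-1] - r or None),
            )
            x._accum(g[sl])

    return Tensor._make(out_data, (x,), backward)


def pad_replicate2d(x: Tensor, pad: tuple[int, int, int, int]) -> Tensor:
    """Edge-replication pad of the two trailing axes: (top, bottom, left, right)."""
    t, b, l, r = pad
    if t == b == l == r == 0:
        return x
    out_data = np.pad(x.data, ((0, 0),) * (x.ndim - 2) + ((t, b), (l, r)), mode="edge")
    H, W = x.data.shape[-2], x.data.shape[-1]

    def backward(g):
        if not x.requires_grad:
            return
        buf = g.copy()
        if t:
            buf[..., t, :] += buf[..., :t, :].sum(axis=-2)
        if b:
            buf[..., t + H - 1, :] += buf[..., t + H :, :].sum(axis=-2)
        core = buf[..., t : t + H, :]
        if l:
            core[..., l] += core[..., :l].sum(axis=-1)
        if r:
            core[..., l + W - 1] += core[..., l + W :].sum(axis=-1)
        x._accum(np.ascontiguousarray(core[..., l : l + W]))

    return Tensor._make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# convolution / pooling / resampling
# ---------------------------------------------------------------------------

def _windows(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Strided sliding-window view (N, C, OH, OW, kh, kw) — no copy."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation.  ``w`` has shape (C_out, C_in/groups, kh, kw)."""
    N, C, H, W = x.data.shape
    C_out, C_in_g, kh, kw = w.data.shape
    if C != C_in_g * groups:
        raise ValueError(
            f"conv2d channel mismatch: input has {C} channels, "
            f"kernel expects {C_in_g * groups} (groups={groups})"
        )
    xp = x.data if padding == 0 else np.pad(
        x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))
    )
    win = _windows(xp, kh, kw, stride)  # (N, C, OH, OW, kh, kw)
    OH, OW = win.shape[2], win.shape[3]
    if groups == 1:
        out = np.tensordot(win, w.data, axes=([1, 4, 5], [1, 2, 3]))
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    elif groups == C and C_out == C:
        out = np.einsum("ncijuv,cuv->ncij", win, w.data[:, 0], optimize=True)
    else:
        per_out = C_out // groups
        chunks = []
        for gidx in range(groups):
            wg = w.data[gidx * per_out : (gidx + 1) * per_out]
            xg = win[:, gidx * C_in_g : (gidx + 1) * C_in_g]
            og = np.tensordot(xg, wg, axes=([1, 4, 5], [1, 2, 3]))
            chunks.append(og.transpose(0, 3, 1, 2))
        out = np.ascontiguousarray(np.concatenate(chunks, axis=1))
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)
    _record_macs(N * OH * OW * C_out * C_in_g * kh * kw)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        # gradient w.r.t. kernel
        if w.requires_grad:
            if groups == 1:
                gw = np.einsum("noij,ncijuv->ocuv", g, win, optimize=True)
            elif groups == C and C_out == C:
                gw = np.einsum("ncij,ncijuv->cuv", g, win, optimize=True)[:, None]
            else:
                per_out = C_out // groups
                gw = np.empty_like(w.data)
                for gidx in range(groups):
                    gw[gidx * per_out : (gidx + 1) * per_out] = np.einsum(
                        "noij,ncijuv->ocuv",
                        g[:, gidx * per_out : (gidx + 1) * per_out],
                        win[:, gidx * C_in_g : (gidx + 1) * C_in_g],
                        optimize=True,
                    )
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # per-window input gradient, then scatter by kernel offset
            if groups == 1:
                gcols = np.einsum("noij,ocuv->ncijuv", g, w.data, optimize=True)
            elif groups == C and C_out == C:
                gcols = np.einsum("ncij,cuv->ncijuv", g, w.data[:, 0], optimize=True)
            else:
                per_out = C_out // groups
                parts = []
                for gidx in range(groups):
                    parts.append(
                        np.einsum(
                            "noij,ocuv->ncijuv",
                            g[:, gidx * per_out : (gidx + 1) * per_out],
                            w.data[gidx * per_out : (gidx + 1) * per_out],
                            optimize=True,
                        )
                    )
                gcols = np.concatenate(parts, axis=1)
            gxp = np.zeros_like(xp)
            span_h = stride * (OH - 1) + 1
            span_w = stride * (OW - 1) + 1
            for u in range(kh):
                for v in range(kw):
                    gxp[:, :, u : u + span_h : stride, v : v + span_w : stride] += gcols[
                        ..., u, v
                    ]
            if padding:
                gxp = gxp[:, :, padding : padding + H, padding : padding + W]
            x._accum(np.ascontiguousarray(gxp))

    return Tensor._make(out, parents, backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``x @ w.T + b`` with ``w`` of shape (out, in)."""
    out = x.matmul(w.transpose(1, 0))
    if b is not None:
        out = out + b
    return out


def maxpool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    stride = stride or kernel
    N, C, H, W = x.data.shape
    if padding:
        xp = np.pad(
            x.data,
            ((0, 0), (0, 0), (padding, padding), (padding, padding)),
            constant_values=-np.inf,
        )
    else:
        xp = x.data
    win = _windows(xp, kernel, kernel, stride)
    N_, C_, OH, OW = win.shape[:4]
    flat = win.reshape(N, C, OH, OW, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gxp = np.zeros_like(xp)
        u = arg // kernel
        v = arg % kernel
        ii, jj = np.meshgrid(np.arange(OH), np.arange(OW), indexing="ij")
        rows = ii[None, None] * stride + u
        cols = jj[None, None] * stride + v
        nn = np.arange(N)[:, None, None, None]
        cc = np.arange(C)[None, :, None, None]
        np.add.at(gxp, (nn, cc, rows, cols), g)
        if padding:
            gxp = gxp[:, :, padding : padding + H, padding : padding + W]
        x._accum(np.ascontiguousarray(gxp))

    return Tensor._make(np.ascontiguousarray(out), (x,), backward)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    out = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g):
        if not x.requires_grad:
            return
        N, C, H, W = x.data.shape
        gr = g.reshape(N, C, H, scale, W, scale).sum(axis=(3, 5))
        x._accum(gr)

    return Tensor._make(out, (x,), backward)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def bce_with_logits(logits: Tensor, targets: np.ndarray, reduction: str = "sum") -> Tensor:
    """Numerically stable binary cross-entropy on raw logits."""
    t = np.asarray(targets, dtype=np.float32)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if reduction == "sum":
        out = loss.sum()
        scale = 1.0
    elif reduction == "mean":
        out = loss.mean()
        scale = 1.0 / loss.size
    else:
        raise ValueError(f"unknown reduction {reduction!r}")

    def backward(g):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-z))
            logits._accum(g * scale * (sig - t))

    return Tensor._make(np.float32(out), (logits,), backward)
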