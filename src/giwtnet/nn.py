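"""Neural-network module framework on top of :mod:`giwtnet.autograd`.

Conventions follow the detector family this package models: convolutions are
bias-free and followed by per-channel batch normalisation (2 learnable
parameters per channel) and SiLU activation, which is what pins the printed
stem-layer parameter count 3·32·9 + 2·32 = 928.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, conv2d, linear, maxpool2d, upsample_nearest2d

__all__ = [
    "Module",
    "Parameter",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "Conv",
    "Linear",
    "MaxPool2d",
    "Upsample",
    "Identity",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module base: parameter registration, train/eval mode, counting."""

    def __init__(self) -> None:
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out = [(prefix + k, v) for k, v in self._params.items()]
        for name, m in self._modules.items():
            out.extend(m.named_parameters(prefix + name + "."))
        return out

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def param_count(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"m{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Conv2d(Module):
    """Plain convolution (optionally biased); no normalisation, no activation."""

    def __init__(self, c_in: int, c_out: int, k: int = 1, stride: int = 1,
                 padding: int | None = None, groups: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        fan_in = (c_in // groups) * k * k
        self.weight = Parameter(_kaiming_uniform(rng, (c_out, c_in // groups, k, k), fan_in))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None
        if bias:
            self._params["bias"] = self.bias

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        shape = (1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            )
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Conv(Module):
    """Conv + BatchNorm + SiLU — the repository-wide convolution block."""

    def __init__(self, c_in: int, c_out: int, k: int = 1, stride: int = 1,
                 padding: int | None = None, groups: int = 1, act: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, stride, padding, groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(c_out)
        self.act = act

    def forward(self, x):
        x = self.bn(self.conv(x))
        return x.silu() if self.act else x


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming_uniform(rng, (c_out, c_in), c_in))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None
        if bias:
            self._params["bias"] = self.bias

    def forward(self, x):
        return linear(x, self.weight, self.bias)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel = kernel
        self.stride = stride or kernel
        self.padding = padding

    def forward(self, x):
        return maxpool2d(x, self.kernel, self.stride, self.padding)


class Upsample(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return upsample_nearest2d(x, self.scale)
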