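"""Neural-network building blocks on top of :mod:`reefdet.autograd`.

Mirrors the familiar Module / Parameter organisation: modules own parameters
and submodules, ``parameters()`` walks the tree, ``state_dict`` round-trips
weights through plain numpy arrays.  Batch-norm keeps non-trainable running
statistics as buffers so trainable-parameter counts stay exact.
"""

from __future__ import annotations

import math
from contextlib import contextmanager
from typing import Iterator

import numpy as np

from .autograd import Parameter, Tensor, concat, conv2d, max_pool2d, upsample_nearest2d

__all__ = [
    "Module", "Sequential", "ModuleList", "Identity", "Conv2d", "BatchNorm2d",
    "Linear", "LayerNorm", "SiLU", "Upsample", "MaxPool2d", "init_rng",
]

_INIT_RNG = np.random.default_rng(0)


@contextmanager
def init_rng(seed: int):
    """Scope the RNG used for weight initialisation (deterministic builds)."""
    global _INIT_RNG
    prev = _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)
    try:
        yield
    finally:
        _INIT_RNG = prev


def _uniform(shape, bound: float) -> np.ndarray:
    return _INIT_RNG.uniform(-bound, bound, size=shape).astype(np.float32)


class Module:
    def __init__(self):
        self.training = True

    # -- tree walking --------------------------------------------------------
    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffer_names", ()):  # set by subclasses
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self._children():
            yield from child.modules()

    def count_parameters(self) -> int:
        """Exact number of trainable scalar parameters."""
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- serialization -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        out.update({name: b.copy() for name, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float32).copy()
        # buffers live as plain attributes on their owning module
        buf_owners: dict[str, tuple[Module, str]] = {}

        def collect(mod: Module, prefix: str):
            for name in getattr(mod, "_buffer_names", ()):
                buf_owners[prefix + name] = (mod, name)
            for cname, child in mod._children():
                collect(child, prefix + cname + ".")

        collect(self, "")
        for name, (mod, attr) in buf_owners.items():
            if name in state:
                setattr(mod, attr, np.asarray(state[name]).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def __getitem__(self, i: int) -> Module:
        return self.layers[i]

    def __len__(self) -> int:
        return len(self.layers)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)

    def append(self, m: Module) -> None:
        self.items.append(m)

    def forward(self, *a, **k):  # pragma: no cover
        raise RuntimeError("ModuleList is a container and cannot be called")


class Identity(Module):
    def forward(self, x):
        return x


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 1, stride: int = 1,
                 padding: int | None = None, bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(_uniform((out_ch, in_ch, kernel, kernel), bound))
        self.bias = Parameter(_uniform((out_ch,), bound)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    _buffer_names = ("running_mean", "running_var")

    def __init__(self, ch: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.weight = Parameter(np.ones(ch, dtype=np.float32))
        self.bias = Parameter(np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * n / max(n - 1, 1)
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * unbiased
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        w = self.weight.reshape(1, self.ch, 1, 1)
        b = self.bias.reshape(1, self.ch, 1, 1)
        return xhat * w + b


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True):
        super().__init__()
        bound = 1.0 / math.sqrt(in_f)
        self.weight = Parameter(_uniform((in_f, out_f), bound))
        self.bias = Parameter(_uniform((out_f,), bound)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.weight + self.bias


class Upsample(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x: Tensor) -> Tensor:
        return upsample_nearest2d(x, self.scale)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int = 1, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.padding)
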