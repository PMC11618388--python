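"""Module system: parameter containers with train/eval state."""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .tensor import Parameter

__all__ = [
    "Module", "ModuleList", "Sequential", "Identity", "Conv2d", "BatchNorm2d",
    "Linear", "LayerNorm", "MaxPool2d", "Upsample", "SiLU", "Sigmoid",
]


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif value is None:
            self._params.pop(name, None)
            self._modules.pop(name, None)
        object.__setattr__(self, name, value)

    # -- traversal --------------------------------------------------------
    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def modules(self):
        for _, m in self.named_modules():
            yield m

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialisation ------------------------------------------------
    def state_dict(self):
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for mname, m in self.named_modules():
            for bname, buf in getattr(m, "_buffers", {}).items():
                out[f"{mname}.{bname}" if mname else bname] = buf.copy()
        return out

    def load_state_dict(self, state):
        params = dict(self.named_parameters())
        bufs = {}
        for mname, m in self.named_modules():
            for bname, buf in getattr(m, "_buffers", {}).items():
                bufs[f"{mname}.{bname}" if mname else bname] = (m, bname, buf)
        for key, val in state.items():
            if key in params:
                assert params[key].data.shape == val.shape, key
                params[key].data[...] = val
            elif key in bufs:
                m, bname, buf = bufs[key]
                buf[...] = val
            else:
                raise KeyError(f"unexpected state entry {key!r}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module):
        name = str(len(self._list))
        self._list.append(mod)
        self._modules[name] = mod
        object.__setattr__(self, name, mod)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = []
        for m in mods:
            name = str(len(self._list))
            self._list.append(m)
            self._modules[name] = m
            object.__setattr__(self, name, m)

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming(shape, fan_in, rng):
    bound = math.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


_INIT_RNG = np.random.default_rng(0)


def seed_init(seed: int):
    """Reseed the weight-initialisation stream (process-wide)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Conv2d(Module):
    def __init__(self, c1, c2, k=1, stride=1, padding=None, dilation=1,
                 bias=False):
        super().__init__()
        self.c1, self.c2, self.k = c1, c2, k
        self.stride = stride
        self.dilation = dilation
        self.padding = (k // 2) * dilation if padding is None else padding
        fan_in = c1 * k * k
        self.weight = Parameter(_kaiming((c2, c1, k, k), fan_in, _INIT_RNG))
        self.bias = Parameter(_kaiming((c2,), fan_in, _INIT_RNG)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class BatchNorm2d(Module):
    def __init__(self, c, eps=1e-3, momentum=0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        if eps <= 0:
            raise ValueError("batch-norm eps must be positive")
        self.weight = Parameter(np.ones(c, dtype=np.float32))   # gamma
        self.bias = Parameter(np.zeros(c, dtype=np.float32))    # beta
        self._buffers = {
            "running_mean": np.zeros(c, dtype=np.float32),
            "running_var": np.ones(c, dtype=np.float32),
        }

    @property
    def running_mean(self):
        return self._buffers["running_mean"]

    @property
    def running_var(self):
        return self._buffers["running_var"]

    def forward(self, x):
        return F.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, self.training,
                              self.momentum, self.eps)


class Linear(Module):
    def __init__(self, c1, c2, bias=True):
        super().__init__()
        self.c1, self.c2 = c1, c2
        self.weight = Parameter(_kaiming((c2, c1), c1, _INIT_RNG))
        self.bias = Parameter(_kaiming((c2,), c1, _INIT_RNG)) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        super().__init__()
        self.dim, self.eps = dim, eps
        self.weight = Parameter(np.ones(dim, dtype=np.float32))
        self.bias = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x):
        return F.layer_norm(x, self.weight, self.bias, self.eps)


class MaxPool2d(Module):
    def __init__(self, k, stride=None, padding=0):
        super().__init__()
        self.k, self.stride, self.padding = k, stride or k, padding

    def forward(self, x):
        return F.maxpool2d(x, self.k, self.stride, self.padding)


class Upsample(Module):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return F.upsample_nearest2x(x)


class SiLU(Module):
    def forward(self, x):
        return F.silu(x)


class Sigmoid(Module):
    def forward(self, x):
        return F.sigmoid(x)
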