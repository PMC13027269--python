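"""Layers, parameter containers and the Adam optimizer for the autograd core.

Follows the usual Module idiom: a Module owns Parameters and sub-Modules,
``parameters()`` walks the tree, ``state_dict``/``load_state_dict`` move
weights by dotted path. Initialisation is always driven by an explicit
``numpy.random.Generator`` so whole-model builds are reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    """Base class: attribute-discovered parameters and training-mode flag."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def _children(self):
        for val in vars(self).values():
            if isinstance(val, Module):
                yield val
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield item

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- serialization -----------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf.copy()
        return state

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Module):
                yield from val.named_buffers(f"{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{key}.{i}.")
            elif isinstance(val, np.ndarray) and name.startswith("running_"):
                yield key, val

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for key, arr in state.items():
            if key in params:
                params[key].data = np.asarray(arr, dtype=params[key].data.dtype)
            elif key in bufs:
                bufs[key][...] = arr
            else:
                raise KeyError(f"unexpected key in state dict: {key}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(he_init(rng, (n_in, n_out), n_in))
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, pad: int | None = None):
        super().__init__()
        if pad is None:
            pad = kernel // 2
        self.stride, self.pad = stride, pad
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(he_init(rng, (c_out, c_in, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    """Per-channel batch normalisation; running stats are used in eval mode."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(-1)).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(-1)).astype(DTYPE)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        g = ag.reshape(self.gamma, (1, -1, 1, 1))
        b = ag.reshape(self.beta, (1, -1, 1, 1))
        return xhat * g + b


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)


class Adam:
    """Adam with optional per-call learning rate override (for schedules)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
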