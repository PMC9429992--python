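"""Layers, parameter containers and the Adam optimizer.

Initialization is He-style scaled normal, drawn from a caller-supplied
``numpy.random.Generator`` so a whole network is reproducible from one seed.
"""

from __future__ import annotations

import numpy as np

from .ops import conv3d, instance_norm
from .tensor import Tensor, leaky_relu, parameter, relu

__all__ = ["Module", "Conv3d", "InstanceNorm", "ConvBlock", "Adam"]


class Module:
    """Base class; collects parameters from attributes recursively."""

    def parameters(self):
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_dict(self):
        return {f"p{i}": p.value for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state):
        for i, p in enumerate(self.parameters()):
            arr = np.asarray(state[f"p{i}"], dtype=p.value.dtype)
            if arr.shape != p.value.shape:
                raise ValueError(
                    f"checkpoint parameter {i} has shape {arr.shape}, "
                    f"expected {p.value.shape}")
            p.value = arr


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1):
        fan_in = cin * k ** 3
        self.w = parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      (cout, cin, k, k, k))
                           .astype(np.float32))
        self.b = parameter(np.zeros(cout, dtype=np.float32))
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, stride=self.stride)


class InstanceNorm(Module):
    def __init__(self, c: int):
        self.gamma = parameter(np.ones(c, dtype=np.float32))
        self.beta = parameter(np.zeros(c, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta)


class ConvBlock(Module):
    """conv(3^3) -> instance norm -> activation, twice."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 activation: str = "relu", norm: bool = True):
        self.c1 = Conv3d(cin, cout, 3, rng)
        self.n1 = InstanceNorm(cout) if norm else None
        self.c2 = Conv3d(cout, cout, 3, rng)
        self.n2 = InstanceNorm(cout) if norm else None
        self.activation = activation

    def _act(self, x):
        return relu(x) if self.activation == "relu" else leaky_relu(x)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.c1(x)
        if self.n1 is not None:
            h = self.n1(h)
        h = self._act(h)
        h = self.c2(h)
        if self.n2 is not None:
            h = self.n2(h)
        return self._act(h)


class Adam:
    """Adam with optional global gradient-norm clipping."""

    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.value)
                 for p in self.params]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                                for g in grads))
            if total > self.clip_norm and total > 0:
                factor = np.float32(self.clip_norm / total)
                grads = [g * factor for g in grads]
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (self.lr * (m / bias1)
                        / (np.sqrt(v / bias2) + self.eps)).astype(np.float32)
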