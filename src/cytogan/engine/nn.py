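"""Neural-network building blocks on top of :mod:`cytogan.engine.tensor`.

Layers follow standard GAN-resnet practice: He-initialized convolutions,
batch normalization where batch statistics are safe, layer normalization
where they are not (the critic, whose gradient penalty is computed
per-sample and must not couple samples through batch statistics).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module container with parameter traversal and train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    params.append(v)
        return params

    def named_state(self) -> dict[str, np.ndarray]:
        """Flat state dict (parameters + buffers) keyed by attribute path."""
        state: dict[str, np.ndarray] = {}

        def visit(obj: "Module", prefix: str):
            for k, v in obj.__dict__.items():
                if isinstance(v, Parameter):
                    state[prefix + k] = v.data
                elif isinstance(v, np.ndarray):
                    state[prefix + k] = v
                elif isinstance(v, Module):
                    visit(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{prefix}{k}.{i}.")

        visit(self, "")
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        own = self.named_state()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing state entries: {sorted(missing)[:5]}")

        def visit(obj: "Module", prefix: str):
            for k, v in obj.__dict__.items():
                if isinstance(v, Parameter):
                    v.data = np.asarray(state[prefix + k], dtype=v.data.dtype)
                elif isinstance(v, np.ndarray):
                    setattr(obj, k, np.asarray(state[prefix + k], dtype=v.dtype))
                elif isinstance(v, Module):
                    visit(v, f"{prefix}{k}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{prefix}{k}.{i}.")

        visit(self, "")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, gain: float = 1.0):
        super().__init__()
        std = gain * np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, std, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return T.matmul(x, T.transpose(self.weight)) + self.bias


class Conv2d(Module):
    """3x3/1x1 convolution via im2col on NHWC maps; 'same' padding default."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 pad: int | None = None, gain: float = 1.0):
        super().__init__()
        if pad is None:
            pad = kernel // 2
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch * kernel * kernel
        std = gain * np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, fan_in)))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        N, H, W, C = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {C}")
        k, s, p = self.kernel, self.stride, self.pad
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        cols = T.unfold(x, k, s, p)                       # (N*L, k*k*C)
        out = T.matmul(cols, T.transpose(self.weight)) + self.bias
        return T.reshape(out, (N, Ho, Wo, self.out_ch))


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 1.0, (num_embeddings, dim)))

    def forward(self, idx) -> Tensor:
        return T.take_rows(self.weight, np.asarray(idx))


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = T.mean_(x, axis=(0, 1, 2), keepdims=True)
            centered = x - mu
            var = T.mean_(centered * centered, axis=(0, 1, 2), keepdims=True)
            with T.no_grad():
                m = self.momentum
                self.running_mean = ((1 - m) * self.running_mean
                                     + m * mu.data.ravel())
                self.running_var = ((1 - m) * self.running_var
                                    + m * var.data.ravel())
            xhat = centered * T.power(var + self.eps, -0.5)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - Tensor(self.running_mean)) * Tensor(inv)
        return xhat * self.gamma + self.beta


class LayerNorm2d(Module):
    """Per-sample normalization over (C,H,W) with per-channel affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        mu = T.mean_(x, axis=(1, 2, 3), keepdims=True)
        centered = x - mu
        var = T.mean_(centered * centered, axis=(1, 2, 3), keepdims=True)
        xhat = centered * T.power(var + self.eps, -0.5)
        return xhat * self.gamma + self.beta


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam optimizer; state is exposed for checkpointing."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.5, 0.9), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.data.astype(p.data.dtype, copy=False)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state(self) -> dict[str, np.ndarray]:
        out = {"t": np.asarray(self.t)}
        for i in range(len(self.params)):
            out[f"m{i}"] = self.m[i]
            out[f"v{i}"] = self.v[i]
        return out

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(state[f"m{i}"]) for i in range(len(self.params))]
        self.v = [np.asarray(state[f"v{i}"]) for i in range(len(self.params))]
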