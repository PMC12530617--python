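"""Building blocks (linear, layer norm, feed-forward) on the autodiff core.

Modules own their parameters as ``Tensor``s with ``requires_grad=True`` and
expose them through ``named_params`` for the optimizer and checkpointing.
Weights use Xavier (Glorot) uniform initialization.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class Module:
    def named_params(self, prefix: str = "") -> dict:
        out = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_params(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_params(f"{key}.{i}."))
        return out

    def load_params(self, params: dict, prefix: str = "") -> None:
        own = self.named_params(prefix)
        missing = set(own) - set(params)
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)[:5]} ...")
        for name, tensor in own.items():
            tensor.data = np.asarray(params[name], dtype=np.float64).reshape(
                tensor.data.shape
            )


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.W = Tensor(xavier_uniform(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        # flatten leading dims so the weight gradient is a single GEMM
        shape = x.data.shape
        if len(shape) > 2:
            d_in = shape[-1]
            out = x.reshape(-1, d_in) @ self.W + self.b
            return out.reshape(*shape[:-1], self.W.data.shape[1])
        return x @ self.W + self.b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(dim), requires_grad=True)
        self.o = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.g + self.o


class FeedForward(Module):
    """Two-layer MLP with ReLU, the transformer position-wise block."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_hidden: int, d_out: int):
        self.fc1 = Linear(rng, d_in, d_hidden)
        self.fc2 = Linear(rng, d_hidden, d_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    if not training or rate <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * Tensor(keep)
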