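"""Neural-network building blocks on the autodiff core.

Layers follow the familiar torch-style Module protocol (``parameters()``,
``train()``/``eval()``) but operate on :class:`milpath.autodiff.Tensor`.
Initialisation is fully determined by the numpy Generator passed in, so a
model built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module", "Linear", "LayerNorm", "Dropout", "FeedForward",
    "MultiHeadSelfAttention", "TransformerEncoderLayer", "GatedAttentionPool",
    "MLP", "AdamW",
]


class Module:
    """Base class: recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Tensor]:
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                yield value
            elif isinstance(value, Module):
                yield from value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.parameters()
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}

        def _collect(mod: Module, prefix: str) -> None:
            for name, value in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor) and value.requires_grad:
                    out[key] = value.data.copy()
                elif isinstance(value, Module):
                    _collect(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            _collect(item, f"{key}.{i}.")
                        elif isinstance(item, Tensor) and item.requires_grad:
                            out[f"{key}.{i}"] = item.data.copy()

        _collect(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        def _assign(mod: Module, prefix: str) -> None:
            for name, value in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor) and value.requires_grad:
                    value.data = np.asarray(state[key], dtype=np.float64).copy()
                elif isinstance(value, Module):
                    _assign(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            _assign(item, f"{key}.{i}.")
                        elif isinstance(item, Tensor) and item.requires_grad:
                            item.data = np.asarray(
                                state[f"{key}.{i}"], dtype=np.float64).copy()

        _assign(self, "")


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(_xavier(rng, in_dim, out_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout driven by an externally supplied Generator."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.drop(self.fc1(x).relu()))


class MultiHeadSelfAttention(Module):
    """Exact multi-head self-attention over a (T, D) token sequence.

    After each forward pass ``last_attention`` holds the (heads, T, T)
    softmax weights as a plain array — the hook used for attention heatmaps.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        if dim % n_heads:
            raise ValueError("embed dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)
        self.drop = Dropout(dropout, rng)
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        t, d = x.shape
        qkv = self.qkv(x).reshape(t, 3, self.n_heads, self.head_dim)
        qkv = qkv.transpose(1, 2, 0, 3)          # (3, H, T, hd)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(self.head_dim))
        attn = scores.softmax(axis=-1)           # (H, T, T)
        self.last_attention = attn.data.copy()
        ctx = attn @ v                           # (H, T, hd)
        ctx = ctx.transpose(1, 0, 2).reshape(t, d)
        return self.out(self.drop(ctx))


class TransformerEncoderLayer(Module):
    """Pre-norm block: x + MHSA(LN(x)); x + FFN(LN(x))."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 dropout: float = 0.0, ff_mult: int = 2):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng, dropout)
        self.ln2 = LayerNorm(dim)
        self.ff = FeedForward(dim, ff_mult * dim, rng, dropout)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.ff(self.ln2(x))


class GatedAttentionPool(Module):
    """Gated attention pooling: a_i ∝ exp(w·(tanh(V h_i) ⊙ σ(U h_i)))."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.V = Linear(dim, hidden, rng)
        self.U = Linear(dim, hidden, rng)
        self.w = Linear(hidden, 1, rng)

    def scores(self, h: Tensor) -> Tensor:
        return self.w(self.V(h).tanh() * self.U(h).sigmoid()).reshape(-1)

    def __call__(self, h: Tensor) -> tuple[Tensor, Tensor]:
        """Pool (N, D) → (D,); also return the softmax weights (N,)."""
        a = self.scores(h).softmax(axis=-1)
        return a @ h, a


class MLP(Module):
    def __init__(self, dims: list[int], rng: np.random.Generator):
        super().__init__()
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class AdamW:
    """AdamW with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)
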