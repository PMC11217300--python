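"""Network building blocks: linear/conv layers, attention, transformer encoder.

All parameters are ``Tensor`` objects with ``requires_grad=True``; modules are
plain Python objects exposing ``parameters()`` and ``named_parameters()``.
Initialisation draws from an explicit ``numpy.random.Generator`` so every model
in the package is bit-reproducible from a seed.
"""

from __future__ import annotations

import json

import numpy as np

from .autograd import Tensor, concat, stack

__all__ = [
    "Module", "Linear", "Conv2d", "Sequential", "ReLU", "Embedding",
    "LayerNorm", "AttentionPool", "SelfAttention", "TransformerEncoderLayer",
    "Adam", "save_params", "load_params", "dropout_mask",
]


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Module:
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Tensor(_kaiming(rng, (n_in, n_out), n_in), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None):
        fan_in = c_in * k * k
        self.weight = Tensor(_kaiming(rng, (c_out, c_in, k, k), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = k // 2 if padding is None else padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class ReLU(Module):
    def __call__(self, x: Tensor) -> Tensor:
        return x.relu()


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def __call__(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(n, dim)), requires_grad=True)

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight.take_rows(np.asarray(idx))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


def dropout_mask(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (inference) or p == 0."""
    if rng is None or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(keep)


def _attend(q: Tensor, k: Tensor, v: Tensor, n_heads: int) -> tuple[Tensor, np.ndarray]:
    """Scaled dot-product attention over the first axis of k/v.

    q: (Lq, D), k/v: (Lk, D).  Returns (pooled (Lq, D), weights (heads, Lq, Lk)).
    """
    lq, d = q.shape
    lk = k.shape[0]
    dh = d // n_heads
    qh = q.reshape(lq, n_heads, dh).transpose(1, 0, 2)   # (h, Lq, dh)
    kh = k.reshape(lk, n_heads, dh).transpose(1, 0, 2)
    vh = v.reshape(lk, n_heads, dh).transpose(1, 0, 2)
    scores = (qh @ kh.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))
    w = scores.softmax(axis=-1)                          # (h, Lq, Lk)
    out = (w @ vh).transpose(1, 0, 2).reshape(lq, d)
    return out, w.data


class AttentionPool(Module):
    """Multi-head attention with a learned query: pools L tokens into one."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        self.query = Tensor(rng.normal(0.0, 0.1, size=(1, dim)), requires_grad=True)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.n_heads = n_heads

    def __call__(self, tokens: Tensor) -> tuple[Tensor, np.ndarray]:
        """tokens (L, D) -> (pooled (D,), weights (L,) averaged over heads)."""
        k = self.wk(tokens)
        v = self.wv(tokens)
        pooled, w = _attend(self.query, k, v, self.n_heads)
        out = self.wo(pooled).reshape(-1)
        return out, w.mean(axis=0)[0]


class ConvexAttentionPool(Module):
    """Attention pooling that outputs a convex combination of its inputs.

    A learned query scores each token (multi-head scores averaged into one
    weight vector); the pooled embedding is sum_i w_i x_i with w >= 0,
    sum w = 1, so a single input token passes through unchanged (weight 1.0)
    and zero-weight tokens do not influence the result.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        self.query = Tensor(rng.normal(0.0, 0.1, size=(1, dim)), requires_grad=True)
        self.wk = Linear(dim, dim, rng)
        self.n_heads = n_heads

    def __call__(self, tokens: Tensor) -> tuple[Tensor, np.ndarray]:
        """tokens (L, D) -> (pooled (D,), weights (L,))."""
        k = self.wk(tokens)
        lk, d = k.shape
        dh = d // self.n_heads
        qh = self.query.reshape(1, self.n_heads, dh).transpose(1, 0, 2)
        kh = k.reshape(lk, self.n_heads, dh).transpose(1, 0, 2)
        scores = (qh @ kh.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))
        w = scores.softmax(axis=-1).mean(axis=0)          # (1, L)
        pooled = (w @ tokens).reshape(-1)
        return pooled, w.data[0]


class SelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.n_heads = n_heads

    def __call__(self, x: Tensor) -> Tensor:
        out, _ = _attend(self.wq(x), self.wk(x), self.wv(x), self.n_heads)
        return self.wo(out)


class TransformerEncoderLayer(Module):
    """Pre-norm transformer encoder layer (self-attention + feed-forward)."""

    def __init__(self, dim: int, n_heads: int, ff_dim: int, rng: np.random.Generator,
                 dropout: float = 0.5):
        self.norm1 = LayerNorm(dim)
        self.attn = SelfAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.dropout = dropout

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        h = self.attn(self.norm1(x))
        x = x + dropout_mask(h, self.dropout, rng)
        h = self.ff2(self.ff1(self.norm2(x)).relu())
        return x + dropout_mask(h, self.dropout, rng)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def save_params(path, module: Module, config: dict | None = None):
    """Single-file versioned checkpoint (.npz with embedded JSON config)."""
    arrays = {name: p.data for name, p in module.named_parameters()}
    meta = json.dumps({"format_version": 1, "config": config or {}})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_params(path, module: Module) -> dict:
    with np.load(path) as zf:
        meta = json.loads(bytes(zf["__meta__"]).decode())
        for name, p in module.named_parameters():
            p.data[...] = zf[name]
    return meta

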