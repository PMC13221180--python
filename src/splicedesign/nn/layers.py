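"""Neural network modules: linear/embedding layers and transformer blocks."""

from __future__ import annotations

import numpy as np

from .tensor import (DEFAULT_DTYPE, Tensor, concat, embedding, layer_norm,
                     scaled_dot_attention, softmax)


class Module:
    """Base class with recursive parameter discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)
        walk(self)
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data[...] = s

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _param(rng: np.random.Generator, shape, std: float = 0.02) -> Tensor:
    return Tensor((rng.normal(0.0, std, size=shape)).astype(DEFAULT_DTYPE),
                  requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 std: float = 0.02):
        self.w = _param(rng, (n_in, n_out), std)
        self.b = Tensor(np.zeros(n_out, dtype=DEFAULT_DTYPE),
                        requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim > 2:
            lead = x.shape[:-1]
            y = x.reshape(-1, x.shape[-1]) @ self.w + self.b
            return y.reshape(*lead, self.w.shape[1])
        return x @ self.w + self.b


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator,
                 std: float = 0.02):
        self.w = _param(rng, (n_vocab, dim), std)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return embedding(self.w, ids)


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.g = Tensor(np.ones(dim, dtype=DEFAULT_DTYPE), requires_grad=True)
        self.b = Tensor(np.zeros(dim, dtype=DEFAULT_DTYPE),
                        requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.g, self.b)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("hidden size must be divisible by head count")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(z: Tensor) -> Tensor:
            return z.reshape(b, t, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        out = scaled_dot_attention(q, k, v)
        out = out.transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.wo(out)


class TransformerLayer(Module):
    """Pre-LN transformer encoder layer with a GELU feed-forward block."""

    def __init__(self, dim: int, n_heads: int, ff_mult: int,
                 rng: np.random.Generator):
        self.ln1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln2 = LayerNorm(dim)
        self.ff1 = Linear(dim, dim * ff_mult, rng)
        self.ff2 = Linear(dim * ff_mult, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        x = x + self.ff2(self.ff1(self.ln2(x)).gelu())
        return x


class TransformerEncoder(Module):
    """Token + position (+ optional auxiliary token) embeddings followed by
    a stack of transformer layers and a final layer norm."""

    def __init__(self, n_vocab: int, max_pos: int, dim: int, n_layers: int,
                 n_heads: int, rng: np.random.Generator, ff_mult: int = 4,
                 n_aux_vocab: int = 0):
        self.tok = Embedding(n_vocab, dim, rng)
        self.pos = Embedding(max_pos, dim, rng)
        self.aux = Embedding(n_aux_vocab, dim, rng) if n_aux_vocab else None
        self.layers = [TransformerLayer(dim, n_heads, ff_mult, rng)
                       for _ in range(n_layers)]
        self.ln = LayerNorm(dim)

    def __call__(self, ids: np.ndarray,
                 aux_ids: np.ndarray | None = None) -> Tensor:
        b, t = ids.shape
        x = self.tok(ids) + self.pos(np.arange(t))
        if aux_ids is not None:
            if self.aux is None:
                raise ValueError("encoder built without auxiliary vocabulary")
            x = x + self.aux(aux_ids)
        for layer in self.layers:
            x = layer(x)
        return self.ln(x)


def cls_vector(hidden: Tensor) -> Tensor:
    """Representation of the first (CLS) position, shape (batch, dim)."""
    b, t, d = hidden.shape
    # slice via reshape-free gather: multiply-select would be wasteful, so
    # use a cheap strided reshape trick
    flat = hidden.reshape(b * t, d)
    idx = np.arange(b) * t
    out = Tensor(flat.data[idx], _parents=(flat,))

    def bw(g):
        full = np.zeros_like(flat.data)
        full[idx] = g
        flat._acc(full)
    out._backward = bw
    return out


__all__ = ["Module", "Linear", "Embedding", "LayerNorm",
           "MultiHeadSelfAttention", "TransformerLayer",
           "TransformerEncoder", "cls_vector", "concat"]
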