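"""Small neural building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, concat

__all__ = ["Module", "Linear", "MultiheadSelfAttention"]


class Module:
    """Container tracking parameters of itself and child modules."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state size mismatch")
        for p, s in zip(params, state):
            p.data = s.copy()


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Parameter(glorot(rng, in_dim, out_dim))
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MultiheadSelfAttention(Module):
    """Scaled dot-product self-attention over a bag of feature vectors.

    softmax(Q K^T / sqrt(d_K)) V per head, heads concatenated and mixed by
    an output projection.  Permutation-equivariant in the bag dimension.
    """

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        n_heads: int = 4,
        d_k: int = 64,
        rng: np.random.Generator | None = None,
    ):
        rng = np.random.default_rng() if rng is None else rng
        self.n_heads = n_heads
        self.d_k = d_k
        self.w_q = [Parameter(glorot(rng, in_dim, d_k)) for _ in range(n_heads)]
        self.w_k = [Parameter(glorot(rng, in_dim, d_k)) for _ in range(n_heads)]
        self.w_v = [Parameter(glorot(rng, in_dim, d_k)) for _ in range(n_heads)]
        self.out_proj = Linear(n_heads * d_k, out_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        heads = []
        scale = 1.0 / np.sqrt(self.d_k)
        for wq, wk, wv in zip(self.w_q, self.w_k, self.w_v):
            q = x @ wq
            k = x @ wk
            v = x @ wv
            att = ((q @ k.T) * scale).softmax(axis=-1)
            heads.append(att @ v)
        return self.out_proj(concat(heads, axis=-1))
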