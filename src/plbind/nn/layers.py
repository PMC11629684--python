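"""Neural layers built on the autodiff engine.

Layers hold :class:`Parameter` tensors and recurse through attributes to
collect them, so any composite module gets ``parameters()`` for free.
Initialization is explicit-seeded: every layer takes an ``rng``
(``numpy.random.Generator``) so a model built twice from the same seed is
bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "MLP",
    "LayerNorm",
    "Dropout",
    "MultiHeadAttention",
    "GRUCell",
    "sinusoidal_positions",
]


class Parameter(Tensor):
    """A tensor that is updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Parameter], seen: set[int]) -> None:
        for value in vars(self).values():
            self._collect_value(value, params, seen)

    @staticmethod
    def _collect_value(value, params, seen) -> None:
        if isinstance(value, Parameter):
            if id(value) not in seen:
                seen.add(id(value))
                params.append(value)
        elif isinstance(value, Module):
            value._collect(params, seen)
        elif isinstance(value, (list, tuple)):
            for item in value:
                Module._collect_value(item, params, seen)
        elif isinstance(value, dict):
            for item in value.values():
                Module._collect_value(item, params, seen)

    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self

    def _set_mode(self, training: bool) -> None:
        self.training = training
        for value in vars(self).values():
            self._mode_value(value, training)

    @staticmethod
    def _mode_value(value, training) -> None:
        if isinstance(value, Module):
            value._set_mode(training)
        elif isinstance(value, (list, tuple)):
            for item in value:
                Module._mode_value(item, training)
        elif isinstance(value, dict):
            for item in value.values():
                Module._mode_value(item, training)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_glorot(rng, in_dim, out_dim, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class MLP(Module):
    """Feed-forward stack; `dims` includes input and output widths."""

    def __init__(self, dims: list[int], rng: np.random.Generator, activation: str = "relu",
                 final_activation: bool = False):
        super().__init__()
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.activation = activation
        self.final_activation = final_activation

    def _act(self, x: Tensor) -> Tensor:
        return getattr(x, self.activation)()

    def __call__(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1 or self.final_activation:
                x = self._act(x)
        return x


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        return normed * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; the mask stream is owned by the layer and seeded."""

    def __init__(self, rate: float, seed: int = 0):
        super().__init__()
        self.rate = float(rate)
        self.rng = np.random.default_rng(seed)

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * mask


class MultiHeadAttention(Module):
    """Scaled dot-product attention; stores the last attention weights.

    ``last_weights`` has shape (heads, n_query, n_key) and every row is a
    probability distribution, which the fusion tests assert directly.
    """

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.last_weights: np.ndarray | None = None

    def _split(self, x: Tensor) -> Tensor:
        n, d = x.shape
        return x.reshape(n, self.n_heads, self.d_head).swapaxes(0, 1)  # (h, n, dh)

    def __call__(self, query: Tensor, key: Tensor, value: Tensor) -> Tensor:
        q = self._split(self.wq(query))
        k = self._split(self.wk(key))
        v = self._split(self.wv(value))
        scores = (q @ k.T) * (1.0 / np.sqrt(self.d_head))
        attn = scores.softmax(axis=-1)  # (h, nq, nk)
        self.last_weights = attn.data.copy()
        mixed = attn @ v  # (h, nq, dh)
        n_q = query.shape[0]
        merged = mixed.swapaxes(0, 1).reshape(n_q, self.n_heads * self.d_head)
        return self.wo(merged)


class GRUCell(Module):
    """Gated recurrent update used by the attentive molecular encoder."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.wz = Linear(2 * dim, dim, rng)
        self.wr = Linear(2 * dim, dim, rng)
        self.wh = Linear(2 * dim, dim, rng)

    def __call__(self, h: Tensor, x: Tensor) -> Tensor:
        hx = concatenate([h, x], axis=-1)
        z = self.wz(hx).sigmoid()
        r = self.wr(hx).sigmoid()
        cand = self.wh(concatenate([h * r, x], axis=-1)).tanh()
        return h * (1.0 - z) + cand * z


def sinusoidal_positions(n: int, d: int) -> np.ndarray:
    """Classic fixed sine/cosine positional encoding, shape (n, d)."""
    pos = np.arange(n)[:, None]
    i = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    enc = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return enc
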