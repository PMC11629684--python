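"""Geometric vector perceptron (GVP) primitives.

A GVP operates on a tuple ``(s, V)`` where ``s`` is an (n, ns) array of
rotation-invariant scalar channels and ``V`` an (n, nv, 3) array of
rotation-equivariant vector channels.  Vector channels only ever enter
the computation through their norms (invariant) or through linear
combinations over the channel axis (equivariant), so the two symmetry
properties hold by construction and the tests can demand them at 1e-5.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate
from .layers import Linear, Module, Parameter, _glorot

__all__ = ["GVP", "GVPStack", "TupleLayerNorm", "tuple_cat"]


def _vec_linear(V: Tensor, weight: Parameter) -> Tensor:
    """Apply an (out, in) channel-mixing matrix to V of shape (n, in, 3)."""
    # (n, in, 3) -> (n, 3, in) @ (in, out) -> (n, 3, out) -> (n, out, 3)
    return (V.swapaxes(-1, -2) @ weight.T).swapaxes(-1, -2)


class GVP(Module):
    """One geometric vector perceptron layer.

    Follows the standard construction: vector channels are mixed to a
    hidden width, their norms join the scalar path, and output vectors
    are gated by a sigmoid of their own norms.
    """

    def __init__(
        self,
        in_dims: tuple[int, int],
        out_dims: tuple[int, int],
        rng: np.random.Generator,
        activation: bool = True,
        vector_gate: bool = True,
    ):
        super().__init__()
        ns_in, nv_in = in_dims
        ns_out, nv_out = out_dims
        self.in_dims, self.out_dims = in_dims, out_dims
        self.activation = activation
        self.vector_gate = vector_gate
        self.nv_hidden = max(nv_in, nv_out, 1)
        if nv_in > 0:
            self.wh = Parameter(_glorot(rng, nv_in, self.nv_hidden, (self.nv_hidden, nv_in)))
            self.ws = Linear(ns_in + self.nv_hidden, ns_out, rng)
        else:
            self.wh = None
            self.ws = Linear(ns_in, ns_out, rng)
        if nv_out > 0:
            if nv_in == 0:
                raise ValueError("cannot produce vector channels from a scalar-only input")
            self.wmu = Parameter(_glorot(rng, self.nv_hidden, nv_out, (nv_out, self.nv_hidden)))
        else:
            self.wmu = None

    def __call__(self, s: Tensor, V: Tensor | None) -> tuple[Tensor, Tensor | None]:
        ns_in, nv_in = self.in_dims
        if nv_in > 0:
            if V is None or V.shape[-2] != nv_in:
                raise ValueError(
                    f"vector channel mismatch: expected {nv_in}, got "
                    f"{None if V is None else V.shape[-2]}"
                )
            Vh = _vec_linear(V, self.wh)
            vnorm = Vh.norm(axis=-1)  # (n, nv_hidden), rotation-invariant
            s_out = self.ws(concatenate([s, vnorm], axis=-1))
        else:
            s_out = self.ws(s)
        if self.activation:
            s_out = s_out.relu()
        V_out: Tensor | None = None
        if self.wmu is not None:
            Vmu = _vec_linear(Vh, self.wmu)  # (n, nv_out, 3)
            if self.vector_gate:
                gate = Vmu.norm(axis=-1, keepdims=True).sigmoid()
                V_out = Vmu * gate
            else:
                V_out = Vmu
        return s_out, V_out


class GVPStack(Module):
    """A fixed-depth composition of GVP layers (depth three for messages)."""

    def __init__(
        self,
        in_dims: tuple[int, int],
        hidden_dims: tuple[int, int],
        out_dims: tuple[int, int],
        n_layers: int,
        rng: np.random.Generator,
    ):
        super().__init__()
        dims = [in_dims] + [hidden_dims] * (n_layers - 1) + [out_dims]
        self.layers = [
            GVP(a, b, rng, activation=(i < n_layers - 1))
            for i, (a, b) in enumerate(zip(dims[:-1], dims[1:]))
        ]

    def __call__(self, s: Tensor, V: Tensor | None) -> tuple[Tensor, Tensor | None]:
        for layer in self.layers:
            s, V = layer(s, V)
        return s, V


class TupleLayerNorm(Module):
    """Layer normalization for (s, V) tuples.

    Scalars get an affine LayerNorm; vector channels are rescaled by the
    root-mean-square of their norms (no learned parameters), which keeps
    the operation equivariant.
    """

    def __init__(self, ns: int, nv: int, eps: float = 1e-5):
        super().__init__()
        from .layers import LayerNorm

        self.scalar_norm = LayerNorm(ns, eps=eps)
        self.nv = nv
        self.eps = eps

    def __call__(self, s: Tensor, V: Tensor | None) -> tuple[Tensor, Tensor | None]:
        s_out = self.scalar_norm(s)
        if V is None or self.nv == 0:
            return s_out, V
        sqnorm = (V**2).sum(axis=-1)  # (n, nv)
        rms = (sqnorm.mean(axis=-1, keepdims=True) + self.eps).sqrt()  # (n, 1)
        V_out = V / rms.reshape(rms.shape[0], 1, 1)
        return s_out, V_out


def tuple_cat(a: tuple[Tensor, Tensor | None], b: tuple[Tensor, Tensor | None]) -> tuple[Tensor, Tensor | None]:
    """Concatenate two (s, V) tuples along the channel axis."""
    s = concatenate([a[0], b[0]], axis=-1)
    if a[1] is None and b[1] is None:
        return s, None
    vecs = [v for v in (a[1], b[1]) if v is not None]
    V = vecs[0] if len(vecs) == 1 else concatenate(vecs, axis=-2)
    return s, V
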