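"""Cross-attention alignment of structure and sequence tokens to the surface.

The encoded-surface tokens act as the shared reference modality: a
transformer encoder self-attends over them, then separate transformer
decoders align the structure tokens and the sequence tokens against the
encoded surface (queries = structure/sequence, keys/values = surface).
Each modality is then average-pooled and the three pooled vectors are
concatenated — surface, structure, sequence, in that order — into one
protein embedding of width 3 d_model.

Surface and structure tokens carry no positional encoding (a point set
and a residue set have no canonical order the attention should exploit);
sequence tokens receive sinusoidal positions.
"""

from __future__ import annotations

import logging

import numpy as np

from .nn import (
    MLP,
    LayerNorm,
    Module,
    MultiHeadAttention,
    Tensor,
    concatenate,
    sinusoidal_positions,
)

logger = logging.getLogger(__name__)

__all__ = ["EncoderBlock", "DecoderBlock", "SurfaceContextEncoder", "CrossAligner",
           "FusionModule", "pool_and_fuse", "project_embeddings_2d"]


class EncoderBlock(Module):
    """Post-norm transformer encoder block (self-attention + feed-forward)."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator, ff_mult: int = 2):
        super().__init__()
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.ff = MLP([d_model, ff_mult * d_model, d_model], rng)
        self.norm2 = LayerNorm(d_model)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self.attn(x, x, x))
        return self.norm2(x + self.ff(x))


class DecoderBlock(Module):
    """Decoder block: query self-attention, cross-attention to memory, feed-forward."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator, ff_mult: int = 2):
        super().__init__()
        self.self_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.cross_attn = MultiHeadAttention(d_model, n_heads, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.norm3 = LayerNorm(d_model)
        self.ff = MLP([d_model, ff_mult * d_model, d_model], rng)

    def __call__(self, queries: Tensor, memory: Tensor) -> Tensor:
        x = self.norm1(queries + self.self_attn(queries, queries, queries))
        x = self.norm2(x + self.cross_attn(x, memory, memory))
        return self.norm3(x + self.ff(x))


class SurfaceContextEncoder(Module):
    """Self-attention stack over the surface tokens."""

    def __init__(self, d_model: int, n_heads: int, n_layers: int, rng: np.random.Generator):
        super().__init__()
        self.blocks = [EncoderBlock(d_model, n_heads, rng) for _ in range(n_layers)]

    def __call__(self, surface_tokens: Tensor) -> Tensor:
        if surface_tokens.shape[0] < 1:
            raise ValueError("need at least one surface token")
        x = surface_tokens
        for block in self.blocks:
            x = block(x)
        return x

    @property
    def last_attention(self) -> np.ndarray | None:
        return self.blocks[-1].attn.last_weights if self.blocks else None


class CrossAligner(Module):
    """Decoder stack aligning one query modality with the encoded surface."""

    def __init__(self, d_model: int, n_heads: int, n_layers: int, rng: np.random.Generator):
        super().__init__()
        self.blocks = [DecoderBlock(d_model, n_heads, rng) for _ in range(n_layers)]

    def __call__(self, queries: Tensor, memory: Tensor) -> Tensor:
        if queries.shape[-1] != memory.shape[-1]:
            raise ValueError(
                f"width mismatch: queries d={queries.shape[-1]} vs surface d={memory.shape[-1]}"
            )
        x = queries
        for block in self.blocks:
            x = block(x, memory)
        return x

    @property
    def last_cross_attention(self) -> np.ndarray | None:
        return self.blocks[-1].cross_attn.last_weights if self.blocks else None


def pool_and_fuse(surface: Tensor, structure: Tensor, sequence: Tensor) -> Tensor:
    """Average-pool each modality over its tokens, then concatenate.

    Output width is exactly 3 d; the order (surface, structure,
    sequence) is fixed.
    """
    for name, tokens in (("surface", surface), ("structure", structure), ("sequence", sequence)):
        if tokens.shape[0] == 0:
            raise ValueError(f"empty modality: {name}")
    return concatenate(
        [surface.mean(axis=0), structure.mean(axis=0), sequence.mean(axis=0)], axis=-1
    )


class FusionModule(Module):
    """Encoder + two decoders + pooling: the multimodal alignment stage.

    ``share_decoders=True`` reuses one decoder stack for both query
    modalities; by default structure and sequence get their own weights.
    The surface contribution to the fused vector is the pooled encoder
    output (the decoders do not modify surface tokens).
    """

    def __init__(
        self,
        d_model: int,
        n_heads: int,
        encoder_layers: int,
        decoder_layers: int,
        rng: np.random.Generator,
        share_decoders: bool = False,
    ):
        super().__init__()
        self.d_model = d_model
        self.encoder = SurfaceContextEncoder(d_model, n_heads, encoder_layers, rng)
        self.align_structure = CrossAligner(d_model, n_heads, decoder_layers, rng)
        self.align_sequence = (
            self.align_structure if share_decoders
            else CrossAligner(d_model, n_heads, decoder_layers, rng)
        )

    def __call__(
        self,
        surface_tokens: Tensor,
        structure_tokens: Tensor,
        sequence_tokens: Tensor,
    ) -> tuple[Tensor, dict[str, Tensor]]:
        seq_pos = sequence_tokens + sinusoidal_positions(sequence_tokens.shape[0], self.d_model)
        encoded_surface = self.encoder(surface_tokens)
        aligned_structure = self.align_structure(structure_tokens, encoded_surface)
        aligned_sequence = self.align_sequence(seq_pos, encoded_surface)
        fused = pool_and_fuse(encoded_surface, aligned_structure, aligned_sequence)
        aligned = {
            "surface": encoded_surface,
            "structure": aligned_structure,
            "sequence": aligned_sequence,
        }
        return fused, aligned


def project_embeddings_2d(embeddings: np.ndarray) -> np.ndarray:
    """Top-2 principal-component projection of stacked embeddings.

    Used to compare per-modality embedding dispersion before and after
    cross-attention alignment.  If the centered matrix has rank < 2 the
    second coordinate is zero-filled (warned).
    """
    from sklearn.decomposition import PCA

    X = np.asarray(embeddings, dtype=np.float64)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 embeddings for a 2D projection")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    n_comp = min(2, rank)
    if n_comp < 2:
        logger.warning("embedding matrix rank %d < 2; zero-filling the second component", rank)
    proj = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
    if proj.shape[1] < 2:
        proj = np.column_stack([proj, np.zeros(X.shape[0])])
    return proj
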