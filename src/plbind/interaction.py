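"""Bipartite protein-ligand contact graph and its global embedding.

An edge links ligand atom i to protein atom j exactly when their
Euclidean distance is strictly below the cutoff (default 5 A); there are
never edges within one atom set.  The encoder runs message passing
across the bipartite edges in both directions, forms per-edge
embeddings from the endpoint states plus an RBF encoding of the edge
distance, pools over edges, and maps the pooled vector through an MLP.
All inputs are distances and atom features, so the embedding is
invariant to rigid motions of the complex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .nn import MLP, Linear, Module, Parameter, Tensor, concatenate, segment_sum
from .structure import rbf_encode

logger = logging.getLogger(__name__)

__all__ = ["HeteroGraph", "build_hetero_graph", "InteractionEncoder", "DEFAULT_CUTOFF"]

DEFAULT_CUTOFF = 5.0
N_EDGE_RBF = 16


@dataclass
class HeteroGraph:
    """Bipartite contact graph G = (V_l, V_p, E)."""

    ligand_index: np.ndarray  # (E,) indices into the ligand atom set
    protein_index: np.ndarray  # (E,) indices into the protein atom set
    distances: np.ndarray  # (E,) A, each strictly < cutoff
    n_ligand: int
    n_protein: int
    cutoff: float

    def __post_init__(self):
        if self.distances.size and self.distances.max() >= self.cutoff:
            raise ValueError("edge at or beyond the cutoff violates the strict < c rule")
        if self.ligand_index.size and (
            self.ligand_index.max() >= self.n_ligand or self.protein_index.max() >= self.n_protein
        ):
            raise ValueError("edge endpoint outside its node set")

    @property
    def n_edges(self) -> int:
        return self.distances.shape[0]


def build_hetero_graph(
    ligand_coords: np.ndarray,
    protein_coords: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
) -> HeteroGraph:
    """All ligand-protein atom pairs with distance strictly below `cutoff`."""
    lig = np.asarray(ligand_coords, dtype=np.float64)
    prot = np.asarray(protein_coords, dtype=np.float64)
    if lig.shape[0] == 0 or prot.shape[0] == 0:
        raise ValueError("both atom sets must be non-empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = np.linalg.norm(lig[:, None, :] - prot[None, :, :], axis=2)
    li, pj = np.nonzero(d < cutoff)
    if li.size == 0:
        logger.info("contact graph has zero edges (all pairs >= %.2f A)", cutoff)
    return HeteroGraph(
        ligand_index=li.astype(np.intp),
        protein_index=pj.astype(np.intp),
        distances=d[li, pj],
        n_ligand=lig.shape[0],
        n_protein=prot.shape[0],
        cutoff=cutoff,
    )


class InteractionEncoder(Module):
    """Cross-edge message passing + edge-level pooling -> global embedding.

    Zero-edge graphs return a learned null embedding, so complexes with
    no close contacts remain representable.
    """

    def __init__(
        self,
        n_ligand_features: int,
        n_protein_features: int,
        rng: np.random.Generator,
        hidden_dim: int = 32,
        out_dim: int = 32,
        n_rounds: int = 2,
        pooling: str = "mean",
    ):
        super().__init__()
        if pooling not in ("mean", "sum"):
            raise ValueError(f"pooling must be 'mean' or 'sum', got {pooling!r}")
        self.pooling = pooling
        self.n_rounds = n_rounds
        self.embed_lig = Linear(n_ligand_features, hidden_dim, rng)
        self.embed_prot = Linear(n_protein_features, hidden_dim, rng)
        self.msg_to_lig = MLP([hidden_dim + N_EDGE_RBF, hidden_dim, hidden_dim], rng)
        self.msg_to_prot = MLP([hidden_dim + N_EDGE_RBF, hidden_dim, hidden_dim], rng)
        self.edge_net = MLP([2 * hidden_dim + N_EDGE_RBF, hidden_dim, hidden_dim], rng)
        self.head = MLP([hidden_dim, hidden_dim, out_dim], rng)
        self.null_embedding = Parameter(np.zeros(out_dim))

    def __call__(
        self,
        graph: HeteroGraph,
        ligand_features: np.ndarray,
        protein_features: np.ndarray,
    ) -> Tensor:
        if ligand_features.shape[0] != graph.n_ligand:
            raise ValueError("ligand feature rows do not match the ligand atom count")
        if protein_features.shape[0] != graph.n_protein:
            raise ValueError("protein feature rows do not match the protein atom count")
        if graph.n_edges == 0:
            return self.null_embedding * 1.0

        h_l = self.embed_lig(Tensor(ligand_features)).relu()
        h_p = self.embed_prot(Tensor(protein_features)).relu()
        rbf = Tensor(rbf_encode(graph.distances, N_EDGE_RBF, 0.0, graph.cutoff))
        li, pj = graph.ligand_index, graph.protein_index

        # per-node mean aggregation: invariant to listing an edge twice
        inv_l = 1.0 / np.maximum(np.bincount(li, minlength=graph.n_ligand), 1)
        inv_p = 1.0 / np.maximum(np.bincount(pj, minlength=graph.n_protein), 1)
        for _ in range(self.n_rounds):
            to_lig = self.msg_to_lig(concatenate([h_p[pj], rbf], axis=-1))
            to_prot = self.msg_to_prot(concatenate([h_l[li], rbf], axis=-1))
            h_l = (h_l + segment_sum(to_lig, li, graph.n_ligand) * inv_l[:, None]).relu()
            h_p = (h_p + segment_sum(to_prot, pj, graph.n_protein) * inv_p[:, None]).relu()

        edge_emb = self.edge_net(concatenate([h_l[li], h_p[pj], rbf], axis=-1))
        pooled = edge_emb.mean(axis=0) if self.pooling == "mean" else edge_emb.sum(axis=0)
        return self.head(pooled.reshape(1, -1)).reshape(-1)
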