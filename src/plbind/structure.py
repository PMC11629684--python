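"""Pocket residue graph and its geometric vector perceptron encoder.

Nodes are the pocket residues (any atom within ``pocket_radius`` of any
ligand atom); edges connect each residue to its k nearest neighbors by
C-alpha distance, in both directions.  Node and edge features follow the
standard GVP-GNN protein featurization: backbone dihedral sines/cosines
and residue identity as scalars, backbone orientation and side-chain
direction unit vectors as vector channels, RBF-encoded distances and
unit displacements on edges.

Message passing follows

    m_ij    = GVPs(concat(h_v(j), h_e(j->i)))          (three GVP layers)
    h_v(i)  = LayerNorm(h_v(i) + 1/k' Dropout(sum_j m_ij))

with k' the number of incoming messages.  Scalar channels are invariant
and vector channels equivariant under rigid motions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import AA_ALPHABET, AtomCloud, _THREE_TO_ONE
from .nn import (
    GVP,
    Dropout,
    GVPStack,
    Module,
    Tensor,
    TupleLayerNorm,
    concatenate,
    segment_sum,
    tuple_cat,
)

logger = logging.getLogger(__name__)

__all__ = ["ResidueGraph", "build_residue_graph", "GVPMessageLayer", "StructureEncoder", "rbf_encode"]

N_NODE_SCALARS = 20 + 6  # residue one-hot + dihedral sin/cos
N_NODE_VECTORS = 3  # forward, backward, side-chain direction
N_EDGE_RBF = 16
N_EDGE_VECTORS = 1
RBF_RANGE = (0.0, 20.0)


def rbf_encode(d: np.ndarray, n_centers: int = N_EDGE_RBF, lo: float = 0.0, hi: float = 20.0) -> np.ndarray:
    """Gaussian radial basis encoding of distances on [lo, hi]."""
    centers = np.linspace(lo, hi, n_centers)
    width = (hi - lo) / (n_centers - 1)
    return np.exp(-((np.asarray(d, dtype=np.float64)[..., None] - centers) ** 2) / (2 * width**2))


@dataclass
class ResidueGraph:
    node_scalars: np.ndarray  # (n, 26)
    node_vectors: np.ndarray  # (n, 3, 3)
    edge_index: np.ndarray  # (2, E): row 0 = source j, row 1 = target i
    edge_scalars: np.ndarray  # (E, 16)
    edge_vectors: np.ndarray  # (E, 1, 3)
    ca_coords: np.ndarray  # (n, 3)
    residue_ids: np.ndarray  # (n,) indices into the parent AtomCloud residues

    def __post_init__(self):
        n = self.node_scalars.shape[0]
        in_deg = np.bincount(self.edge_index[1], minlength=n)
        if n and in_deg.min() < 1:
            raise ValueError("every node needs at least one incoming edge")

    @property
    def n_nodes(self) -> int:
        return self.node_scalars.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def in_degree(self) -> np.ndarray:
        return np.bincount(self.edge_index[1], minlength=self.n_nodes).astype(np.float64)


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    return float(np.arctan2(y, x))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-9 else np.zeros(3)


def build_residue_graph(
    atoms: AtomCloud,
    ligand_coords: np.ndarray,
    pocket_radius: float = 8.0,
    k_neighbors: int = 16,
) -> ResidueGraph:
    """Residue graph over the pocket, with GVP-style geometric features."""
    ligand_coords = np.asarray(ligand_coords, dtype=np.float64)
    # pocket residues: any atom within pocket_radius of any ligand atom
    d_min = np.min(
        np.linalg.norm(atoms.coords[:, None, :] - ligand_coords[None, :, :], axis=2), axis=1
    )
    pocket_res = np.unique(atoms.residue_index[d_min < pocket_radius])
    if pocket_res.size == 0:
        raise ValueError(f"no residue has an atom within pocket_radius={pocket_radius} A of the ligand")

    all_ids, bb = atoms.backbone_coords(("N", "CA", "C"))
    bb_of = {int(r): bb[i] for i, r in enumerate(all_ids)}
    kept = [int(r) for r in pocket_res if int(r) in bb_of]
    dropped = len(pocket_res) - len(kept)
    if dropped:
        logger.warning("%d pocket residues lack a complete N/CA/C backbone; dropped", dropped)
    if not kept:
        raise ValueError("no pocket residue has a complete backbone")

    n = len(kept)
    ca = np.array([bb_of[r][1] for r in kept])

    # --- node scalar features: residue one-hot + phi/psi/omega sin & cos
    letters = []
    for r in kept:
        sel = np.nonzero(atoms.residue_index == r)[0][0]
        letters.append(_THREE_TO_ONE.get(str(atoms.res_name[sel]), "X"))
    onehot = np.zeros((n, 20))
    for i, aa in enumerate(letters):
        if aa in AA_ALPHABET:
            onehot[i, AA_ALPHABET.index(aa)] = 1.0

    dihed = np.zeros((n, 3))
    for i, r in enumerate(kept):
        prev_bb, next_bb = bb_of.get(r - 1), bb_of.get(r + 1)
        this = bb_of[r]
        if prev_bb is not None:
            dihed[i, 0] = _dihedral(prev_bb[2], this[0], this[1], this[2])  # phi
        if next_bb is not None:
            dihed[i, 1] = _dihedral(this[0], this[1], this[2], next_bb[0])  # psi
            dihed[i, 2] = _dihedral(this[1], this[2], next_bb[0], next_bb[1])  # omega
    node_scalars = np.concatenate([onehot, np.sin(dihed), np.cos(dihed)], axis=1)

    # --- node vector features: backbone orientations + side-chain direction
    node_vectors = np.zeros((n, N_NODE_VECTORS, 3))
    for i, r in enumerate(kept):
        if bb_of.get(r + 1) is not None:
            node_vectors[i, 0] = _unit(bb_of[r + 1][1] - ca[i])
        if bb_of.get(r - 1) is not None:
            node_vectors[i, 1] = _unit(bb_of[r - 1][1] - ca[i])
        mask = (atoms.residue_index == r) & (atoms.atom_name == "CB")
        sel = np.nonzero(mask)[0]
        if sel.size:
            node_vectors[i, 2] = _unit(atoms.coords[sel[0]] - ca[i])

    # --- edges: k nearest neighbors by C-alpha distance, both directions
    src, dst = [], []
    if n == 1:
        src, dst = [0], [0]  # self-loop fallback
    else:
        dmat = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
        np.fill_diagonal(dmat, np.inf)
        k_eff = min(k_neighbors, n - 1)
        for i in range(n):
            nbrs = np.argsort(dmat[i], kind="stable")[:k_eff]
            for j in nbrs:
                src.append(int(j))
                dst.append(int(i))
    edge_index = np.array([src, dst], dtype=np.intp)
    disp = ca[edge_index[0]] - ca[edge_index[1]]  # x_j - x_i
    dist = np.linalg.norm(disp, axis=1)
    edge_scalars = rbf_encode(dist, N_EDGE_RBF, *RBF_RANGE)
    with np.errstate(invalid="ignore", divide="ignore"):
        edge_vectors = (disp / np.maximum(dist, 1e-9)[:, None])[:, None, :]

    return ResidueGraph(
        node_scalars=node_scalars,
        node_vectors=node_vectors,
        edge_index=edge_index,
        edge_scalars=edge_scalars,
        edge_vectors=edge_vectors,
        ca_coords=ca,
        residue_ids=np.asarray(kept, dtype=np.intp),
    )


class GVPMessageLayer(Module):
    """One message-passing round: three-GVP messages + normalized residual update."""

    def __init__(
        self,
        node_dims: tuple[int, int],
        edge_dims: tuple[int, int],
        rng: np.random.Generator,
        dropout: float = 0.1,
        dropout_seed: int = 0,
    ):
        super().__init__()
        ns, nv = node_dims
        es, ev = edge_dims
        self.message_net = GVPStack((ns + es, nv + ev), node_dims, node_dims, n_layers=3, rng=rng)
        self.norm = TupleLayerNorm(ns, nv)
        self.drop_s = Dropout(dropout, seed=dropout_seed)
        self.drop_v = Dropout(dropout, seed=dropout_seed + 1)

    def message(self, h_s: Tensor, h_V: Tensor, e_s: Tensor, e_V: Tensor) -> tuple[Tensor, Tensor]:
        """m_ij = GVPs(concat(h_v(j), h_e(j->i))) for pre-gathered inputs."""
        s, V = tuple_cat((h_s, h_V), (e_s, e_V))
        return self.message_net(s, V)

    def update(
        self,
        h_s: Tensor,
        h_V: Tensor,
        msg_s: Tensor,
        msg_V: Tensor,
        dst: np.ndarray,
        n_nodes: int,
    ) -> tuple[Tensor, Tensor]:
        """h_v(i) <- LayerNorm(h_v(i) + 1/k' Dropout(sum_j m_ij))."""
        k_prime = np.bincount(dst, minlength=n_nodes).astype(np.float64)
        if k_prime.min() < 1:
            raise ValueError("a node received zero messages (k' = 0)")
        sum_s = segment_sum(msg_s, dst, n_nodes)
        sum_V = segment_sum(msg_V, dst, n_nodes)
        inv_k = 1.0 / k_prime
        new_s = h_s + self.drop_s(sum_s) * inv_k[:, None]
        new_V = h_V + self.drop_v(sum_V) * inv_k[:, None, None]
        return self.norm(new_s, new_V)

    def __call__(self, h_s, h_V, graph: ResidueGraph, e_s: Tensor, e_V: Tensor):
        src, dst = graph.edge_index
        ms, mV = self.message(h_s[src], h_V[src], e_s, e_V)
        return self.update(h_s, h_V, ms, mV, dst, graph.n_nodes)


class StructureEncoder(Module):
    """Residue graph -> per-residue scalar structure tokens."""

    def __init__(
        self,
        rng: np.random.Generator,
        hidden_scalar: int = 32,
        hidden_vector: int = 4,
        n_layers: int = 3,
        dropout: float = 0.1,
        dropout_seed: int = 0,
    ):
        super().__init__()
        node_dims = (hidden_scalar, hidden_vector)
        edge_dims = (N_EDGE_RBF, N_EDGE_VECTORS)
        self.embed_nodes = GVP((N_NODE_SCALARS, N_NODE_VECTORS), node_dims, rng, activation=False)
        self.layers = [
            GVPMessageLayer(node_dims, edge_dims, rng, dropout=dropout, dropout_seed=dropout_seed + 10 * i)
            for i in range(n_layers)
        ]

    def __call__(self, graph: ResidueGraph) -> Tensor:
        h_s, h_V = self.embed_nodes(Tensor(graph.node_scalars), Tensor(graph.node_vectors))
        e_s, e_V = Tensor(graph.edge_scalars), Tensor(graph.edge_vectors)
        for layer in self.layers:
            h_s, h_V = layer(h_s, h_V, graph, e_s, e_V)
        return h_s
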