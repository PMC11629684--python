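"""Ligand 2D-graph featurization and attention-based graph encoding.

The ligand is a heavy-atom molecular graph (hydrogens stripped for the
topology; 3D coordinates are kept separately for the interaction graph).
The encoder follows the attentive-fingerprint design: several rounds of
neighbor attention with gated (GRU) state updates at the atom level,
then attentive readout rounds against a molecule-level super node.
Attention weights over each neighborhood form a probability
distribution and are exposed for interpretability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import GRUCell, Linear, Module, Tensor, concatenate, segment_softmax, segment_sum

__all__ = ["LigandGraph", "featurize_ligand", "LigandEncoder", "LIGAND_ELEMENTS"]

LIGAND_ELEMENTS = ("C", "N", "O", "S", "P", "F", "CL", "BR", "I", "OTHER")
_HYBRIDIZATIONS = ("SP", "SP2", "SP3", "SP3D", "SP3D2")
_BOND_TYPES = ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")

N_ATOM_FEATURES = len(LIGAND_ELEMENTS) + 6 + 1 + 1 + len(_HYBRIDIZATIONS)
N_BOND_FEATURES = len(_BOND_TYPES) + 2


@dataclass
class LigandGraph:
    """Atom/bond feature matrices plus coordinates.

    Atom feature layout (length 23): element one-hot (10) | degree
    one-hot 0..5 (6) | formal charge (1) | aromatic flag (1) |
    hybridization one-hot (5).  Bond feature layout (length 6): bond
    type one-hot (4) | conjugated (1) | in-ring (1).  The bond list is
    stored directed, both ways, and is symmetric by construction.
    """

    atom_features: np.ndarray  # (n_atoms, 23)
    bond_index: np.ndarray  # (2, 2*n_bonds) directed, symmetric
    bond_features: np.ndarray  # (2*n_bonds, 6)
    coords: np.ndarray  # (n_atoms, 3)
    elements: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.atom_features.shape[0] != self.coords.shape[0]:
            raise ValueError("atom feature rows must equal atom count")
        if self.bond_index.size:
            fwd = set(map(tuple, self.bond_index.T.tolist()))
            rev = {(b, a) for a, b in fwd}
            if fwd != rev:
                raise ValueError("bond list must be symmetric")

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bond_index.shape[1] // 2

    @property
    def center(self) -> np.ndarray:
        return self.coords.mean(axis=0)


def featurize_ligand(mol, coords: np.ndarray | None = None) -> LigandGraph:
    """Build a :class:`LigandGraph` from an RDKit molecule.

    If `coords` is omitted, the molecule's first conformer is used.
    """
    from rdkit import Chem

    if mol.GetNumAtoms() == 0:
        raise ValueError("ligand has no atoms")
    if coords is None:
        if mol.GetNumConformers() == 0:
            raise ValueError("ligand has no conformer and no coords were given")
        coords = np.asarray(mol.GetConformer().GetPositions(), dtype=np.float64)
    coords = np.asarray(coords, dtype=np.float64)

    n = mol.GetNumAtoms()
    feats = np.zeros((n, N_ATOM_FEATURES))
    elements = []
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol().upper()
        elements.append(sym)
        col = LIGAND_ELEMENTS.index(sym) if sym in LIGAND_ELEMENTS else LIGAND_ELEMENTS.index("OTHER")
        feats[i, col] = 1.0
        off = len(LIGAND_ELEMENTS)
        feats[i, off + min(atom.GetDegree(), 5)] = 1.0
        feats[i, off + 6] = atom.GetFormalCharge()
        feats[i, off + 7] = 1.0 if atom.GetIsAromatic() else 0.0
        hyb = str(atom.GetHybridization())
        if hyb in _HYBRIDIZATIONS:
            feats[i, off + 8 + _HYBRIDIZATIONS.index(hyb)] = 1.0

    src, dst, bfeats = [], [], []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        row = np.zeros(N_BOND_FEATURES)
        btype = str(bond.GetBondType())
        if btype in _BOND_TYPES:
            row[_BOND_TYPES.index(btype)] = 1.0
        row[len(_BOND_TYPES)] = 1.0 if bond.GetIsConjugated() else 0.0
        row[len(_BOND_TYPES) + 1] = 1.0 if bond.IsInRing() else 0.0
        for s, t in ((a, b), (b, a)):
            src.append(s)
            dst.append(t)
            bfeats.append(row)

    bond_index = np.array([src, dst], dtype=np.intp) if src else np.zeros((2, 0), dtype=np.intp)
    bond_features = np.array(bfeats) if bfeats else np.zeros((0, N_BOND_FEATURES))
    return LigandGraph(
        atom_features=feats,
        bond_index=bond_index,
        bond_features=bond_features,
        coords=coords,
        elements=tuple(elements),
    )


class LigandEncoder(Module):
    """Attentive message passing over the molecular graph + attentive readout.

    ``atom_rounds`` neighbor-attention/GRU updates refine atom states;
    ``mol_rounds`` attention steps against a molecule super node produce
    the graph-level embedding.  ``last_atom_attention`` (per directed
    bond) and ``last_readout_attention`` (per atom) hold the most recent
    normalized attention weights.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        hidden_dim: int = 128,
        atom_rounds: int = 3,
        mol_rounds: int = 2,
    ):
        super().__init__()
        self.hidden_dim = hidden_dim
        self.atom_rounds = atom_rounds
        self.mol_rounds = mol_rounds
        self.embed = Linear(N_ATOM_FEATURES, hidden_dim, rng)
        self.att_score = Linear(2 * hidden_dim + N_BOND_FEATURES, 1, rng)
        self.att_value = Linear(hidden_dim + N_BOND_FEATURES, hidden_dim, rng)
        self.atom_gru = GRUCell(hidden_dim, rng)
        self.read_score = Linear(2 * hidden_dim, 1, rng)
        self.read_value = Linear(hidden_dim, hidden_dim, rng)
        self.mol_gru = GRUCell(hidden_dim, rng)
        self.last_atom_attention: np.ndarray | None = None
        self.last_readout_attention: np.ndarray | None = None

    def __call__(self, graph: LigandGraph) -> Tensor:
        h = self.embed(Tensor(graph.atom_features)).leaky_relu()
        n = graph.n_atoms
        src, dst = graph.bond_index
        bf = Tensor(graph.bond_features)

        if src.size:
            for _ in range(self.atom_rounds):
                pair = concatenate([h[dst], h[src], bf], axis=-1)
                logits = self.att_score(pair).leaky_relu().reshape(src.size)
                alpha = segment_softmax(logits, dst, n)
                self.last_atom_attention = alpha.data.copy()
                values = self.att_value(concatenate([h[src], bf], axis=-1)).tanh()
                context = segment_sum(values * alpha.reshape(-1, 1), dst, n)
                h = self.atom_gru(h, context.relu())

        # attentive readout against a super node initialised as the atom mean
        mol = h.mean(axis=0, keepdims=True)
        for _ in range(self.mol_rounds):
            mol_rep = Tensor(np.ones((n, 1))) @ mol
            pair = concatenate([mol_rep, h], axis=-1)
            logits = self.read_score(pair).leaky_relu().reshape(n)
            alpha = logits.softmax(axis=0)
            self.last_readout_attention = alpha.data.copy()
            context = (self.read_value(h).tanh() * alpha.reshape(-1, 1)).sum(axis=0, keepdims=True)
            mol = self.mol_gru(mol, context.relu())
        return mol.reshape(self.hidden_dim)
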