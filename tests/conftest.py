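"""Shared fixtures: tiny structures, molecules, and reduced configs."""

from __future__ import annotations

import numpy as np
import pytest

from plbind.config import RunConfig
from plbind.data_io import ATOM_VOCAB_22, AtomCloud


def tiny_config(seed: int = 0) -> RunConfig:
    """Very small model config for fast unit tests."""
    cfg = RunConfig()
    cfg.seed = seed
    cfg.surface.pocket_k = 32
    cfg.surface.embed_dim = 8
    cfg.surface.chem_dim = 8
    cfg.fusion.d_model = 16
    cfg.fusion.n_heads = 2
    cfg.fusion.encoder_layers = 1
    cfg.fusion.decoder_layers = 1
    cfg.sequence.width = 8
    cfg.ligand.hidden_dim = 16
    cfg.structure.hidden_scalar = 16
    cfg.structure.hidden_vector = 2
    cfg.structure.n_layers = 1
    cfg.structure.dropout = 0.0
    cfg.interaction.hidden_dim = 16
    cfg.interaction.out_dim = 16
    cfg.train.head_hidden = 16
    return cfg


@pytest.fixture
def small_run_config() -> RunConfig:
    return tiny_config()


def make_atom_cloud(coords, elements=None, residue_index=None, atom_names=None) -> AtomCloud:
    """Helper to build an AtomCloud from bare coordinates."""
    from plbind.data_io import element_index

    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    elements = elements if elements is not None else ["C"] * n
    residue_index = (
        np.asarray(residue_index, dtype=np.intp) if residue_index is not None
        else np.zeros(n, dtype=np.intp)
    )
    atom_names = atom_names if atom_names is not None else ["X"] * n
    return AtomCloud(
        coords=coords,
        atom_type=np.array([element_index(e) for e in elements], dtype=np.intp),
        residue_index=residue_index,
        chain_id=np.array(["A"] * n),
        atom_name=np.array(atom_names),
        element=np.array(elements),
        res_name=np.array(["ALA"] * n),
        vocab=ATOM_VOCAB_22,
    )


@pytest.fixture
def mol_from_smiles():
    """Build an RDKit molecule with planar coordinates from SMILES."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    def _make(smiles: str, add_hs: bool = False):
        mol = Chem.MolFromSmiles(smiles)
        if add_hs:
            mol = Chem.AddHs(mol)
        AllChem.Compute2DCoords(mol)
        return mol

    return _make


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation matrix via QR."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
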