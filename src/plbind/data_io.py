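"""Structure / ligand / affinity-index parsing and leakage-safe splits.

Protein structures (PDB, mmCIF) are read through biotite; ligands (SDF,
MOL2) through RDKit.  The affinity index follows the PDBbind
``INDEX_*_data`` text dialect: whitespace-separated columns
``code  resolution  year  -log(Kd/Ki)  ...``, with ``#`` comment lines.

The test split is always exactly the provided core set, and core
complexes are removed from the training and validation pools so held-out
benchmark complexes can never leak into training.
"""

from __future__ import annotations

import json
import logging

from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ATOM_VOCAB_22",
    "ATOM_VOCAB_6",
    "AtomCloud",
    "AffinityRecord",
    "SplitManifest",
    "LigandStructure",
    "ParseError",
    "element_index",
    "read_protein_structure",
    "write_protein_structure",
    "read_ligand",
    "parse_affinity_index",
    "make_splits",
]


class ParseError(ValueError):
    """Raised when an input file violates its format."""


# 22-symbol element vocabulary: the six basic protein elements, then the
# halogens and metals common in deposited structures, then a catch-all.
ATOM_VOCAB_22: tuple[str, ...] = (
    "H", "C", "N", "O", "P", "S",
    "SE", "F", "CL", "BR", "I",
    "B", "MG", "ZN", "CA", "FE", "MN", "NA", "K", "CU", "NI",
    "OTHER",
)
# Reduced variant: hydrogen, carbon, nitrogen, oxygen, phosphorus, sulfur.
ATOM_VOCAB_6: tuple[str, ...] = ("H", "C", "N", "O", "P", "S")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "SEC": "U", "MSE": "M",
}

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def element_index(symbol: str, vocab: tuple[str, ...] = ATOM_VOCAB_22) -> int:
    """Map an element symbol to its vocabulary index.

    Symbols outside the vocabulary map to the catch-all index (or to
    carbon for the reduced vocabulary, which has no catch-all slot) with
    a logged warning.
    """
    sym = symbol.strip().upper()
    if sym in vocab:
        return vocab.index(sym)
    logger.warning("element %r outside the %d-type vocabulary", symbol, len(vocab))
    return vocab.index("OTHER") if "OTHER" in vocab else vocab.index("C")


@dataclass
class AtomCloud:
    """Protein atoms: coordinates (A), typed elements, residue membership."""

    coords: np.ndarray  # (n, 3) float
    atom_type: np.ndarray  # (n,) int, index into `vocab`
    residue_index: np.ndarray  # (n,) int, 0-based in order of appearance
    chain_id: np.ndarray  # (n,) str
    atom_name: np.ndarray  # (n,) str, e.g. "CA"
    element: np.ndarray  # (n,) str symbols
    res_name: np.ndarray  # (n,) str three-letter codes
    vocab: tuple[str, ...] = ATOM_VOCAB_22

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        self.atom_type = np.asarray(self.atom_type, dtype=np.intp)
        if self.atom_type.min(initial=0) < 0 or self.atom_type.max(initial=0) >= len(self.vocab):
            raise ValueError("atom_type outside vocabulary range")

    def __len__(self) -> int:
        return self.coords.shape[0]

    def backbone_coords(self, names: tuple[str, ...] = ("N", "CA", "C")) -> tuple[np.ndarray, np.ndarray]:
        """Per-residue backbone coordinates.

        Returns ``(res_ids, coords)`` where coords has shape
        (n_complete_residues, len(names), 3); residues missing any of the
        requested atoms are skipped.
        """
        out_ids, out_coords = [], []
        for rid in np.unique(self.residue_index):
            mask = self.residue_index == rid
            row = []
            for name in names:
                sel = np.where(mask & (self.atom_name == name))[0]
                if sel.size == 0:
                    row = None
                    break
                row.append(self.coords[sel[0]])
            if row is not None:
                out_ids.append(int(rid))
                out_coords.append(row)
        if not out_ids:
            return np.empty(0, dtype=np.intp), np.empty((0, len(names), 3))
        return np.asarray(out_ids, dtype=np.intp), np.asarray(out_coords)


@dataclass
class AffinityRecord:
    complex_id: str
    y: float
    y_hat: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.y):
            raise ValueError(f"non-finite affinity for {self.complex_id}")


@dataclass
class SplitManifest:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise ValueError(f"split sets overlap: {sorted(overlap)[:5]}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "train": sorted(self.train_ids),
            "val": sorted(self.val_ids),
            "test": sorted(self.test_ids),
            "seed": self.seed,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitManifest":
        obj = json.loads(Path(path).read_text())
        return cls(obj["train"], obj["val"], obj["test"], obj["seed"])


@dataclass
class LigandStructure:
    """A parsed small molecule: RDKit Mol plus its 3D coordinates (A)."""

    mol: object  # rdkit.Chem.Mol
    coords: np.ndarray  # (n_atoms, 3)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def center(self) -> np.ndarray:
        return self.coords.mean(axis=0)


# --------------------------------------------------------------------------
# protein structures
# --------------------------------------------------------------------------

def _atom_array_from_file(path: Path):
    import biotite.structure.io.pdb as pdb
    import biotite.structure.io.pdbx as pdbx

    suffix = path.suffix.lower()
    try:
        if suffix in (".cif", ".mmcif", ".pdbx"):
            f = pdbx.CIFFile.read(str(path))
            return pdbx.get_structure(f, model=1, altloc="first")
        f = pdb.PDBFile.read(str(path))
        return pdb.get_structure(f, model=1, altloc="first")
    except Exception as err:  # noqa: BLE001 - reraise with file context
        raise ParseError(f"cannot parse structure file {path}: {err}") from err


def read_protein_structure(
    path: str | Path,
    vocab: tuple[str, ...] = ATOM_VOCAB_22,
    keep_hydrogens: bool = True,
) -> tuple[AtomCloud, dict[str, str]]:
    """Read a PDB/mmCIF file into an :class:`AtomCloud` plus per-chain sequences.

    One atom per ATOM/HETATM record is retained (first altloc).  Waters
    are dropped.  Sequences are derived from the residue records in chain
    order; non-standard residues become ``X``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _atom_array_from_file(path)
    mask = arr.res_name != "HOH"
    if not keep_hydrogens:
        mask &= arr.element != "H"
    arr = arr[mask]
    if arr.array_length() == 0:
        raise ParseError(f"{path}: no atoms after filtering")

    chain_ids = np.asarray(arr.chain_id, dtype=str)
    res_ids = np.asarray(arr.res_id)
    res_names = np.asarray(arr.res_name, dtype=str)
    # residue_index: 0-based, in order of appearance, contiguous over the file
    keys = list(zip(chain_ids.tolist(), res_ids.tolist()))
    index_of: dict[tuple[str, int], int] = {}
    residue_index = np.empty(len(keys), dtype=np.intp)
    for i, key in enumerate(keys):
        if key not in index_of:
            index_of[key] = len(index_of)
        residue_index[i] = index_of[key]

    atom_type = np.array([element_index(e, vocab) for e in arr.element], dtype=np.intp)
    cloud = AtomCloud(
        coords=np.asarray(arr.coord, dtype=np.float64),
        atom_type=atom_type,
        residue_index=residue_index,
        chain_id=chain_ids,
        atom_name=np.asarray(arr.atom_name, dtype=str),
        element=np.asarray(arr.element, dtype=str),
        res_name=res_names,
        vocab=vocab,
    )
    sequences: dict[str, str] = {}
    for (chain, _rid), idx in index_of.items():
        first_atom = int(np.nonzero(residue_index == idx)[0][0])
        letter = _THREE_TO_ONE.get(res_names[first_atom], "X")
        sequences[chain] = sequences.get(chain, "") + letter
    return cloud, sequences


def write_protein_structure(cloud: AtomCloud, path: str | Path) -> None:
    """Write an :class:`AtomCloud` as a PDB file (fixture/export path)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = len(cloud)
    arr = struc.AtomArray(n)
    arr.coord = cloud.coords.astype(np.float32)
    arr.chain_id = cloud.chain_id
    arr.res_id = cloud.residue_index + 1
    arr.res_name = cloud.res_name
    arr.atom_name = cloud.atom_name
    arr.element = cloud.element
    arr.hetero = np.zeros(n, dtype=bool)
    f = pdb.PDBFile()
    pdb.set_structure(f, arr)
    f.write(str(path))


# --------------------------------------------------------------------------
# ligands
# --------------------------------------------------------------------------

def read_ligand(path: str | Path, strip_hydrogens: bool = True) -> LigandStructure:
    """Read an SDF or MOL2 ligand into an RDKit graph plus 3D coordinates."""
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        mol = next(iter(supplier), None)
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
    else:
        raise ParseError(f"unsupported ligand format: {path}")
    if mol is None:
        raise ParseError(f"RDKit could not parse ligand file {path}")
    try:
        Chem.SanitizeMol(mol)
    except Exception as err:  # noqa: BLE001
        raise ParseError(f"{path}: sanitization failed: {err}") from err
    if strip_hydrogens:
        mol = Chem.RemoveHs(mol)
    if mol.GetNumAtoms() == 0:
        raise ParseError(f"{path}: zero-atom ligand record")
    if mol.GetNumConformers() == 0:
        raise ParseError(f"{path}: ligand has no 3D coordinates")
    coords = np.asarray(mol.GetConformer().GetPositions(), dtype=np.float64)
    return LigandStructure(mol=mol, coords=coords)


# --------------------------------------------------------------------------
# affinity index
# --------------------------------------------------------------------------

def parse_affinity_index(path: str | Path) -> list[AffinityRecord]:
    """Parse a PDBbind-style index file into affinity records.

    Data lines carry at least four whitespace-separated fields; the
    fourth is the measured -log affinity.  ``#`` lines are comments.
    """
    records: list[AffinityRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected >= 4 fields, got {len(fields)}")
        code = fields[0]
        try:
            y = float(fields[3])
        except ValueError as err:
            raise ParseError(f"{path}:{lineno}: bad affinity value {fields[3]!r}") from err
        if code in seen:
            raise ParseError(f"{path}:{lineno}: duplicate complex id {code!r}")
        seen.add(code)
        records.append(AffinityRecord(complex_id=code, y=y))
    return records


# --------------------------------------------------------------------------
# splits
# --------------------------------------------------------------------------

def make_splits(
    records: list[AffinityRecord],
    core_ids: set[str],
    n_val: int,
    seed: int,
    val_pool: set[str] | None = None,
) -> SplitManifest:
    """Build a leakage-safe train/val/test split.

    ``test`` is exactly the core set; ``val`` is drawn without
    replacement (seeded) from ``val_pool`` minus the core set (by
    default, every non-core record — at benchmark scale the caller
    passes the refined-set ids); ``train`` is everything else.
    """
    all_ids = [r.complex_id for r in records]
    id_set = set(all_ids)
    missing = set(core_ids) - id_set
    if missing:
        logger.warning("%d core ids absent from records: %s", len(missing), sorted(missing)[:5])
    test = sorted(set(core_ids) & id_set)
    pool_ids = (val_pool & id_set) if val_pool is not None else id_set
    pool = sorted(pool_ids - set(core_ids))
    if n_val > len(pool):
        raise ValueError(f"n_val={n_val} exceeds validation pool of size {len(pool)}")
    rng = np.random.default_rng(seed)
    val = sorted(rng.choice(pool, size=n_val, replace=False).tolist()) if n_val else []
    taken = set(test) | set(val)
    train = [cid for cid in all_ids if cid not in taken]
    return SplitManifest(train_ids=train, val_ids=val, test_ids=test, seed=seed)
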