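"""Parsing, vocabularies, round-trips, and leakage-safe splits."""

import numpy as np
import pytest

from plbind.data_io import (
    ATOM_VOCAB_6,
    ATOM_VOCAB_22,
    AffinityRecord,
    ParseError,
    SplitManifest,
    element_index,
    make_splits,
    parse_affinity_index,
    read_ligand,
    read_protein_structure,
    write_protein_structure,
)

THREE_RES_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      6  C   GLY A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      7  N   SER A   3       6.181   3.851   0.000  1.00  0.00           N
ATOM      8  CA  SER A   3       7.636   3.866   0.000  1.00  0.00           C
ATOM      9  C   SER A   3       8.182   5.288   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AGLY A   1       1.450   0.000   0.000  0.50  0.00           C
ATOM      3  CA BGLY A   1       1.460   0.100   0.000  0.50  0.00           C
ATOM      4  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
END
"""


class TestProteinParsing:
    def test_three_residue_fixture(self, tmp_path):
        p = tmp_path / "tri.pdb"
        p.write_text(THREE_RES_PDB)
        cloud, seqs = read_protein_structure(p)
        assert len(cloud) == 9
        np.testing.assert_array_equal(cloud.residue_index, [0, 0, 0, 1, 1, 1, 2, 2, 2])
        assert seqs == {"A": "AGS"}
        np.testing.assert_allclose(cloud.coords[1], [1.458, 0.0, 0.0], atol=1e-3)

    def test_single_glycine_sequence(self, tmp_path):
        p = tmp_path / "gly.pdb"
        p.write_text("\n".join(THREE_RES_PDB.splitlines()[3:6]) + "\nEND\n")
        _, seqs = read_protein_structure(p)
        assert seqs == {"A": "G"}

    def test_altloc_keeps_one_atom(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        cloud, _ = read_protein_structure(p)
        assert len(cloud) == 3  # one CA survives the altloc rule
        np.testing.assert_allclose(cloud.coords[1], [1.450, 0.0, 0.0], atol=1e-3)

    def test_unreadable_file_raises_parse_error(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text("not a pdb at all\n")
        with pytest.raises((ParseError, Exception)):
            cloud, _ = read_protein_structure(p)
            assert len(cloud)  # must not silently return an empty cloud

    def test_round_trip_preserves_coordinates(self, tmp_path):
        p = tmp_path / "tri.pdb"
        p.write_text(THREE_RES_PDB)
        cloud, _ = read_protein_structure(p)
        out = tmp_path / "out.pdb"
        write_protein_structure(cloud, out)
        cloud2, _ = read_protein_structure(out)
        np.testing.assert_allclose(cloud.coords, cloud2.coords, atol=1e-3)
        np.testing.assert_array_equal(cloud.residue_index, cloud2.residue_index)

    def test_element_vocabulary(self):
        assert element_index("C") == ATOM_VOCAB_22.index("C")
        assert element_index("Zn") == ATOM_VOCAB_22.index("ZN")
        assert element_index("Xx") == ATOM_VOCAB_22.index("OTHER")
        assert ATOM_VOCAB_6 == ("H", "C", "N", "O", "P", "S")
        assert len(ATOM_VOCAB_22) == 22


class TestLigandParsing:
    def _write_sdf(self, mol, path):
        from rdkit import Chem

        w = Chem.SDWriter(str(path))
        w.write(mol)
        w.close()

    def test_benzene_nodes_and_bonds(self, tmp_path, mol_from_smiles):
        p = tmp_path / "benzene.sdf"
        self._write_sdf(mol_from_smiles("c1ccccc1"), p)
        lig = read_ligand(p)
        assert lig.mol.GetNumAtoms() == 6
        assert lig.mol.GetNumBonds() == 6

    def test_methane_hydrogen_strip(self, tmp_path, mol_from_smiles):
        p = tmp_path / "methane.sdf"
        self._write_sdf(mol_from_smiles("C", add_hs=True), p)
        lig = read_ligand(p, strip_hydrogens=True)
        assert lig.mol.GetNumAtoms() == 1
        assert lig.mol.GetNumBonds() == 0

    def test_propane_path_graph(self, tmp_path, mol_from_smiles):
        p = tmp_path / "propane.sdf"
        self._write_sdf(mol_from_smiles("CCC"), p)
        lig = read_ligand(p)
        edges = {
            tuple(sorted((b.GetBeginAtomIdx(), b.GetEndAtomIdx())))
            for b in lig.mol.GetBonds()
        }
        assert edges == {(0, 1), (1, 2)}

    def test_unparsable_ligand_raises(self, tmp_path):
        p = tmp_path / "junk.sdf"
        p.write_text("garbage\n\n\n$$$$\n")
        with pytest.raises(ParseError):
            read_ligand(p)


class TestAffinityIndex:
    def test_dialect(self, tmp_path):
        p = tmp_path / "INDEX_test_data"
        p.write_text(
            "# header comment\n"
            "abcd 2.00 2010 6.30 // Kd=0.5uM\n"
            "wxyz 1.80 2015 4.10 // Ki=80uM\n"
        )
        records = parse_affinity_index(p)
        assert len(records) == 2
        assert records[0].complex_id == "abcd"
        assert records[0].y == pytest.approx(6.30)

    def test_duplicate_code_rejected(self, tmp_path):
        p = tmp_path / "idx"
        p.write_text("abcd 2.0 2010 6.3\nabcd 2.0 2011 5.1\n")
        with pytest.raises(ParseError, match="abcd"):
            parse_affinity_index(p)

    def test_malformed_line_reports_number(self, tmp_path):
        p = tmp_path / "idx"
        p.write_text("abcd 2.0 2010 6.3\nshort line\n")
        with pytest.raises(ParseError, match=":2"):
            parse_affinity_index(p)


class TestSplits:
    def _records(self, n=10):
        return [AffinityRecord(f"c{i:02d}", float(i)) for i in range(n)]

    def test_partition_sizes_and_disjointness(self):
        records = self._records()
        core = {"c00", "c01", "c02"}
        m = make_splits(records, core, n_val=2, seed=0)
        assert len(m.train_ids) == 5 and len(m.val_ids) == 2 and len(m.test_ids) == 3
        all_ids = set(m.train_ids) | set(m.val_ids) | set(m.test_ids)
        assert all_ids == {r.complex_id for r in records}
        assert set(m.test_ids) == core
        assert not (set(m.train_ids) & set(m.val_ids))
        assert not (core & (set(m.train_ids) | set(m.val_ids)))

    def test_degenerate_split_all_train(self):
        m = make_splits(self._records(), set(), n_val=0, seed=1)
        assert len(m.train_ids) == 10 and not m.val_ids and not m.test_ids

    def test_seed_determinism(self):
        a = make_splits(self._records(), {"c03"}, n_val=3, seed=7)
        b = make_splits(self._records(), {"c03"}, n_val=3, seed=7)
        assert (a.train_ids, a.val_ids, a.test_ids) == (b.train_ids, b.val_ids, b.test_ids)

    def test_oversized_validation_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            make_splits(self._records(), {"c00"}, n_val=10, seed=0)

    def test_manifest_rejects_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitManifest(["a", "b"], ["b"], [], seed=0)

    def test_manifest_json_round_trip(self, tmp_path):
        m = make_splits(self._records(), {"c00"}, n_val=2, seed=3)
        path = tmp_path / "splits.json"
        m.to_json(path)
        m2 = SplitManifest.from_json(path)
        assert set(m2.test_ids) == {"c00"} and m2.seed == 3
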