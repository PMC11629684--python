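"""Surface sampling, pocket selection, features, and invariance."""

import numpy as np
import pytest

from plbind.surface import (
    ChemicalFeatureNet,
    QuasiGeodesicConv,
    SurfaceEncoder,
    SurfacePointCloud,
    chemical_neighborhoods,
    geometric_features,
    quasi_geodesic_distances,
    sample_surface,
    select_pocket,
)

from conftest import make_atom_cloud, random_rotation


class TestSampling:
    def test_normals_unit_length(self):
        rng = np.random.default_rng(0)
        atoms = make_atom_cloud(rng.normal(scale=4, size=(25, 3)))
        surf = sample_surface(atoms, seed=0)
        np.testing.assert_allclose(np.linalg.norm(surf.normals, axis=1), 1.0, atol=1e-6)

    def test_single_atom_level_set_radius(self):
        surf = sample_surface(np.zeros((1, 3)), seed=0, n_per_atom=200)
        radii = np.linalg.norm(surf.points, axis=1)
        assert abs(radii.mean() - 1.05) / 1.05 < 0.10

    def test_two_distant_atoms_give_disjoint_shells(self):
        atoms = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        surf = sample_surface(atoms, seed=0)
        d_mid = np.linalg.norm(surf.points - np.array([50.0, 0, 0]), axis=1)
        assert d_mid.min() > 40.0

    def test_rigid_motion_matched_seed(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(scale=3, size=(15, 3))
        R, t = random_rotation(rng), np.array([4.0, -2.0, 1.0])
        s1 = sample_surface(make_atom_cloud(coords), seed=5)
        s2 = sample_surface(make_atom_cloud(coords @ R.T + t), seed=5)
        # moved original surface should interleave with the re-sampled one
        moved = s1.points @ R.T + t
        from scipy.spatial import cKDTree

        d, _ = cKDTree(s2.points).query(moved)
        assert np.median(d) < 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            sample_surface(np.zeros((5, 3)), seed=0)
        with pytest.raises(ValueError, match="resolution"):
            sample_surface(np.zeros((1, 3)), resolution=0.0)


class TestPocketSelection:
    @pytest.mark.parametrize("K", [256, 512, 1024])
    def test_matches_brute_force_oracle(self, K):
        rng = np.random.default_rng(K)
        pts = rng.uniform(-30, 30, size=(2000, 3))
        nrm = rng.normal(size=(2000, 3))
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        surf = SurfacePointCloud(points=pts, normals=nrm)
        center = rng.uniform(-5, 5, size=3)
        pocket = select_pocket(surf, center, K)
        d = np.linalg.norm(pts - center, axis=1)
        oracle = set(np.argsort(d, kind="stable")[:K].tolist())
        assert set(pocket.indices.tolist()) == oracle
        assert len(pocket) == min(K, 2000)

    def test_k_larger_than_cloud(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(300, 3))
        surf = SurfacePointCloud(points=pts, normals=_unit_rows(rng.normal(size=(300, 3))))
        assert len(select_pocket(surf, np.zeros(3), 512)) == 300

    def test_tie_break_prefers_lower_index(self):
        pts = np.array([[1.0, 0, 0], [2.0, 0, 0], [-2.0, 0, 0], [3.0, 0, 0], [5.0, 0, 0]])
        nrm = np.tile([0.0, 0, 1], (5, 1))
        pocket = select_pocket(SurfacePointCloud(points=pts, normals=nrm), np.zeros(3), 2)
        # distances (1, 2, 2, 3, 5): index 1 beats index 2 at the tie
        assert set(pocket.indices.tolist()) == {0, 1}


def _unit_rows(x):
    return x / np.linalg.norm(x, axis=1, keepdims=True)


class TestChemicalFeatures:
    def test_neighbor_sets_match_brute_force(self):
        rng = np.random.default_rng(2)
        atoms = make_atom_cloud(rng.normal(scale=5, size=(20, 3)),
                                elements=list(rng.choice(["C", "N", "O", "S"], 20)))
        point = rng.normal(size=(1, 3))
        onehot, inv = chemical_neighborhoods(point, atoms, k_atoms=16)
        d = np.linalg.norm(atoms.coords - point[0], axis=1)
        oracle = np.argsort(d, kind="stable")[:16]
        np.testing.assert_allclose(inv[0], np.minimum(1.0 / d[oracle], 2.0))
        expected_types = atoms.atom_type[oracle]
        np.testing.assert_array_equal(np.argmax(onehot[0], axis=1), expected_types)

    def test_padding_when_few_atoms(self):
        atoms = make_atom_cloud([[0, 0, 0], [3, 0, 0]])
        onehot, inv = chemical_neighborhoods(np.array([[1.0, 0, 0]]), atoms, k_atoms=16)
        assert onehot.shape == (1, 16, 22)
        assert np.ptp(inv[0, 2:]) == 0  # padded with the farthest neighbor

    def test_net_deterministic_and_rigid_invariant(self):
        rng = np.random.default_rng(4)
        atoms = make_atom_cloud(rng.normal(scale=4, size=(30, 3)))
        pts = rng.normal(scale=4, size=(10, 3))
        net = ChemicalFeatureNet(22, 8, np.random.default_rng(0))
        oh, inv = chemical_neighborhoods(pts, atoms)
        out1 = net(oh, inv).data
        np.testing.assert_array_equal(out1, net(oh, inv).data)

        R, t = random_rotation(rng), np.array([1.0, 2.0, 3.0])
        atoms_r = make_atom_cloud(atoms.coords @ R.T + t)
        oh2, inv2 = chemical_neighborhoods(pts @ R.T + t, atoms_r)
        out2 = net(oh2, inv2).data
        assert np.abs(out2 - out1).max() / np.abs(out1).max() <= 1e-4


class TestCurvature:
    def test_sphere(self):
        rng = np.random.default_rng(0)
        p = _unit_rows(rng.normal(size=(1500, 3)))
        surf = SurfacePointCloud(points=2.0 * p, normals=p)
        curv = geometric_features(surf, scales=(1.0,))
        H, K = curv[:, 0].mean(), curv[:, 1].mean()
        assert abs(H - 0.5) / 0.5 < 0.10
        assert abs(K - 0.25) / 0.25 < 0.20

    def test_plane(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(-5, 5, size=(600, 2))
        surf = SurfacePointCloud(
            points=np.column_stack([xy, np.zeros(600)]), normals=np.tile([0.0, 0, 1], (600, 1))
        )
        curv = geometric_features(surf, scales=(2.0,))
        assert np.abs(curv[:, 0]).max() < 0.02

    def test_saddle_negative_gaussian(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(-2, 2, size=(500, 2))
        z = (xy[:, 0] ** 2 - xy[:, 1] ** 2) / 4
        pts = np.column_stack([xy, z])
        pts[0] = 0.0
        grad = np.column_stack([-xy[:, 0] / 2, xy[:, 1] / 2, np.ones(500)])
        grad[0] = [0, 0, 1]
        surf = SurfacePointCloud(points=pts, normals=_unit_rows(grad))
        curv = geometric_features(surf, scales=(1.0,), indices=np.array([0]))
        assert curv[0, 1] < 0  # K = -1/4 at the origin

    def test_sparse_neighborhood_zeroed(self, caplog):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-50, 50, size=(12, 3))
        surf = SurfacePointCloud(points=pts, normals=_unit_rows(rng.normal(size=(12, 3))))
        with caplog.at_level("WARNING"):
            curv = geometric_features(surf, scales=(0.5,))
        assert np.all(curv == 0.0)
        assert "neighbors" in caplog.text


class TestQuasiGeodesicConv:
    def test_distance_formula_antipodal(self):
        # opposed normals double the Euclidean distance
        pts = np.array([[0.0, 0, 2], [0.0, 0, -2]])
        nrm = np.array([[0.0, 0, 1], [0.0, 0, -1]])
        qg = quasi_geodesic_distances(pts, nrm)
        assert qg[0, 1] == pytest.approx(4.0 * (2 - (-1)) / 3 * 3)  # = |dx|*(2-<n,n>) = 4*3
        assert qg[0, 1] == pytest.approx(3 * np.linalg.norm(pts[0] - pts[1]))

    def test_zero_radius_reduces_to_pointwise(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 3))
        nrm = _unit_rows(rng.normal(size=(8, 3)))
        feats = rng.normal(size=(8, 4))
        conv = QuasiGeodesicConv(4, 6, np.random.default_rng(0), radius=1e-9)
        out = conv(_t(feats), quasi_geodesic_distances(pts, nrm)).data
        pointwise = conv(_t(feats), np.full((8, 8), 1e6) - np.diag(np.full(8, 1e6))).data
        np.testing.assert_allclose(out, pointwise, atol=1e-12)

    def test_isolated_point_passes_through(self):
        pts = np.array([[0.0, 0, 0], [100.0, 0, 0], [101.5, 0, 0]])
        nrm = np.tile([0.0, 0, 1], (3, 1))
        feats = np.eye(3)
        conv = QuasiGeodesicConv(3, 3, np.random.default_rng(1), radius=2.0)
        w = conv.window(quasi_geodesic_distances(pts, nrm))
        np.testing.assert_allclose(w[0], [1.0, 0, 0])  # isolated: only itself


class TestPipelineInvariance:
    def test_surface_embedding_rigid_motion(self):
        rng = np.random.default_rng(7)
        atoms = make_atom_cloud(rng.normal(scale=4, size=(30, 3)),
                                elements=list(rng.choice(["C", "N", "O"], 30)))
        surf = sample_surface(atoms, seed=2)
        idx = np.arange(min(40, len(surf)))
        enc = SurfaceEncoder(22, np.random.default_rng(0), chem_dim=8, out_dim=8)
        oh, inv = chemical_neighborhoods(surf.points[idx], atoms)
        cv = geometric_features(surf, indices=idx)
        qg = quasi_geodesic_distances(surf.points[idx], surf.normals[idx])
        ref = enc(oh, inv, cv, qg).data

        for trial in range(20):
            rr = np.random.default_rng(100 + trial)
            R, t = random_rotation(rr), rr.uniform(-10, 10, 3)
            atoms_r = make_atom_cloud(atoms.coords @ R.T + t, elements=list(atoms.element))
            surf_r = SurfacePointCloud(points=surf.points @ R.T + t, normals=surf.normals @ R.T)
            oh2, inv2 = chemical_neighborhoods(surf_r.points[idx], atoms_r)
            cv2 = geometric_features(surf_r, indices=idx)
            qg2 = quasi_geodesic_distances(surf_r.points[idx], surf_r.normals[idx])
            out = enc(oh2, inv2, cv2, qg2).data
            assert np.abs(out - ref).max() / np.abs(ref).max() <= 1e-4


def _t(x):
    from plbind.nn import Tensor

    return Tensor(x)
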