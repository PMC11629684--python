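"""Oriented point-cloud protein surfaces and their learned embeddings.

The surface is generated on-the-fly from the atomic point cloud: points
are initialized around atoms, projected onto a level set of a smooth
(softmin) distance field by gradient descent, trimmed to a thin band
around the level set, thinned to a target sampling density, and oriented
by the normalized gradient of the field.  The pocket is the K points
nearest the ligand center.  Per-point features combine an atom-type
neighborhood (chemical) with multi-scale mean/Gaussian curvature
(geometric), and a stack of quasi-geodesic convolutions turns them into
rotation/translation-invariant scalar embeddings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .data_io import AtomCloud
from .nn import MLP, Linear, Module, Tensor

logger = logging.getLogger(__name__)

__all__ = [
    "SurfacePointCloud",
    "PocketSurface",
    "sample_surface",
    "select_pocket",
    "chemical_neighborhoods",
    "ChemicalFeatureNet",
    "geometric_features",
    "quasi_geodesic_distances",
    "QuasiGeodesicConv",
    "SurfaceEncoder",
    "CURVATURE_SCALES",
]

#: default atom "radius" / softmin temperature and level-set offset, in A
ATOM_RADIUS = 1.05
LEVEL = 1.05
BAND = 0.05
CURVATURE_SCALES = (1.0, 2.0, 5.0, 10.0)


@dataclass
class SurfacePointCloud:
    points: np.ndarray  # (n, 3) A
    normals: np.ndarray  # (n, 3), unit outward
    source: AtomCloud | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        self.normals = np.asarray(self.normals, dtype=np.float64)
        norms = np.linalg.norm(self.normals, axis=1)
        if self.normals.size and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("surface normals must be unit length")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class PocketSurface:
    indices: np.ndarray  # (K,) into the parent surface
    points: np.ndarray  # (K, 3)
    normals: np.ndarray  # (K, 3)
    K: int
    features: np.ndarray | None = None  # optional cached feature matrix

    def __len__(self) -> int:
        return self.indices.shape[0]


# --------------------------------------------------------------------------
# smooth distance field
# --------------------------------------------------------------------------

def _smooth_distance(x: np.ndarray, atoms: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Softmin distance field and its gradient at points `x`.

    ``f(x) = -sigma * log sum_k exp(-|x - a_k| / sigma)`` approaches the
    distance to the nearest atom; its gradient points away from the
    atoms, so it orients the surface outward.
    """
    diff = x[:, None, :] - atoms[None, :, :]  # (m, k, 3)
    dist = np.linalg.norm(diff, axis=2)  # (m, k)
    dmin = dist.min(axis=1, keepdims=True)
    w = np.exp(-(dist - dmin) / sigma)
    wsum = w.sum(axis=1, keepdims=True)
    f = (dmin - sigma * np.log(wsum)).ravel()
    unit = diff / np.maximum(dist, 1e-12)[:, :, None]
    grad = (w[:, :, None] * unit).sum(axis=1) / wsum
    return f, grad


def sample_surface(
    atoms: AtomCloud | np.ndarray,
    resolution: float = 1.0,
    seed: int = 0,
    sigma: float = ATOM_RADIUS,
    level: float = LEVEL,
    band: float = BAND,
    n_per_atom: int = 40,
    n_steps: int = 10,
    step_size: float = 0.5,
    remove_interior: bool = True,
) -> SurfacePointCloud:
    """Sample an oriented point cloud on the softmin-distance level set.

    Deterministic for a fixed seed.  ``resolution`` is the target density
    in points per square Angstrom, enforced by voxel-grid thinning with
    cell side ``1/sqrt(resolution)``.
    """
    source = atoms if isinstance(atoms, AtomCloud) else None
    coords = atoms.coords if isinstance(atoms, AtomCloud) else np.asarray(atoms, dtype=np.float64)
    if coords.shape[0] < 1:
        raise ValueError("need at least one atom")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if coords.shape[0] > 1 and np.allclose(coords.ptp(axis=0) if hasattr(coords, "ptp") else np.ptp(coords, axis=0), 0.0):
        raise ValueError("degenerate input: all atoms coincident")

    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(coords.shape[0], n_per_atom, 3))
    dirs /= np.linalg.norm(dirs, axis=2, keepdims=True)
    x = (coords[:, None, :] + level * dirs).reshape(-1, 3)

    for _ in range(n_steps):
        f, grad = _smooth_distance(x, coords, sigma)
        x = x - step_size * (f - level)[:, None] * grad

    f, grad = _smooth_distance(x, coords, sigma)
    keep = np.abs(f - level) < band
    x, grad = x[keep], grad[keep]
    if x.shape[0] == 0:
        raise ValueError("empty surface after level-set trimming")
    normals = grad / np.linalg.norm(grad, axis=1, keepdims=True)

    if remove_interior and x.shape[0] > 0:
        # visibility heuristic: stepping outward along the normal must
        # increase the distance field, otherwise the point faces the interior
        f_out, _ = _smooth_distance(x + 1.0 * normals, coords, sigma)
        exterior = f_out > f[keep] + 0.25
        if exterior.any():
            x, normals = x[exterior], normals[exterior]

    # voxel-grid thinning to the target density (deterministic)
    cell = 1.0 / np.sqrt(resolution)
    vox = np.floor((x - x.min(axis=0)) / cell).astype(np.int64)
    order = np.lexsort((np.arange(x.shape[0]), vox[:, 2], vox[:, 1], vox[:, 0]))
    _, first = np.unique(vox[order], axis=0, return_index=True)
    sel = np.sort(order[first])
    return SurfacePointCloud(points=x[sel], normals=normals[sel], source=source)


def select_pocket(surface: SurfacePointCloud, ligand_center: np.ndarray, K: int) -> PocketSurface:
    """The ``min(K, n)`` surface points closest to the ligand center.

    Ties at the cut boundary resolve to the lower index (stable sort).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n = len(surface)
    if n == 0:
        raise ValueError("empty surface")
    d = np.linalg.norm(surface.points - np.asarray(ligand_center, dtype=np.float64), axis=1)
    order = np.argsort(d, kind="stable")
    idx = np.sort(order[: min(K, n)])
    return PocketSurface(
        indices=idx,
        points=surface.points[idx],
        normals=surface.normals[idx],
        K=K,
    )


# --------------------------------------------------------------------------
# chemical features
# --------------------------------------------------------------------------

def chemical_neighborhoods(
    points: np.ndarray,
    atoms: AtomCloud,
    k_atoms: int = 16,
    inv_dist_cap: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """For each point, its `k_atoms` nearest atoms' types and inverse distances.

    Returns ``(type_onehot, inv_dist)`` with shapes (n, k, n_types) and
    (n, k).  If the protein has fewer than `k_atoms` atoms, the farthest
    neighbor is repeated (logged).  Equivalent to a brute-force k-nearest
    scan; ties resolve to the lower atom index.
    """
    if len(atoms) == 0:
        raise ValueError("empty atom cloud")
    if k_atoms < 1:
        raise ValueError("k_atoms must be >= 1")
    pts = np.asarray(points, dtype=np.float64)
    d = np.linalg.norm(pts[:, None, :] - atoms.coords[None, :, :], axis=2)
    k_eff = min(k_atoms, len(atoms))
    order = np.argsort(d, axis=1, kind="stable")[:, :k_eff]
    if k_eff < k_atoms:
        logger.warning("only %d atoms available for k_atoms=%d; padding", k_eff, k_atoms)
        pad = np.repeat(order[:, -1:], k_atoms - k_eff, axis=1)
        order = np.concatenate([order, pad], axis=1)
    ndist = np.take_along_axis(d, order, axis=1)
    inv = np.minimum(1.0 / np.maximum(ndist, 1e-9), inv_dist_cap)
    n_types = len(atoms.vocab)
    onehot = np.eye(n_types)[atoms.atom_type[order]]
    return onehot, inv


class ChemicalFeatureNet(Module):
    """Learnable map from atom-neighborhood descriptors to chemical features.

    Each of the k neighbors contributes (type one-hot + inverse distance)
    through a shared three-layer perceptron; contributions are
    sum-pooled.  All inputs are types and distances, so the output is
    invariant to rigid motions by construction.
    """

    def __init__(self, n_types: int, out_dim: int, rng: np.random.Generator, hidden: int = 16):
        super().__init__()
        self.n_types = n_types
        self.mlp = MLP([n_types + 1, hidden, hidden, out_dim], rng)

    def __call__(self, onehot: np.ndarray, inv_dist: np.ndarray) -> Tensor:
        n, k, t = onehot.shape
        x = np.concatenate([onehot, inv_dist[:, :, None]], axis=2).reshape(n * k, t + 1)
        per_neighbor = self.mlp(Tensor(x))
        return per_neighbor.reshape(n, k, -1).sum(axis=1)


# --------------------------------------------------------------------------
# geometric features
# --------------------------------------------------------------------------

def _tangent_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    axis = np.zeros(3)
    axis[np.argmin(np.abs(normal))] = 1.0
    t1 = np.cross(normal, axis)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return t1, t2


def geometric_features(
    surface: SurfacePointCloud,
    scales: tuple[float, ...] = CURVATURE_SCALES,
    min_neighbors: int = 5,
    indices: np.ndarray | None = None,
) -> np.ndarray:
    """Mean and Gaussian curvature per point at each scale.

    A quadric ``w = a u^2 + b uv + c v^2 + d u + e v + f`` is fit by
    least squares to the neighbors within each scale radius, expressed
    in the tangent frame of the point; H and K follow from the Monge
    patch formulas (H signed so that a sphere with outward normals has
    H = +1/R).  Both are invariant to rigid motions and to the in-plane
    choice of tangent basis.  Columns: (H_s1, K_s1, H_s2, K_s2, ...).

    `indices` restricts evaluation to a subset of points (e.g. the
    pocket); neighborhoods still come from the full surface.
    """
    pts, nrm = surface.points, surface.normals
    if pts.shape[0] < 10:
        raise ValueError("need at least 10 surface points for curvature estimation")
    eval_idx = np.arange(pts.shape[0]) if indices is None else np.asarray(indices, dtype=np.intp)
    n = eval_idx.shape[0]
    tree = cKDTree(pts)
    out = np.zeros((n, 2 * len(scales)))
    n_degenerate = 0
    for si, scale in enumerate(scales):
        if scale <= 0:
            raise ValueError("curvature scales must be positive")
        neighbor_lists = tree.query_ball_point(pts[eval_idx], r=scale)
        for row in range(n):
            i = int(eval_idx[row])
            nb = neighbor_lists[row]
            if len(nb) < min_neighbors:
                n_degenerate += 1
                continue
            t1, t2 = _tangent_basis(nrm[i])
            rel = pts[nb] - pts[i]
            u, v, w = rel @ t1, rel @ t2, rel @ nrm[i]
            A = np.column_stack([u**2, u * v, v**2, u, v, np.ones_like(u)])
            # ridge-regularized normal equations: keeps degenerate
            # neighborhoods well-posed.  The penalty weights (1, 1/2, 1)
            # on (a, b, c) equal the Frobenius norm of the quadric form,
            # and lam is built from u^2+v^2, so the solution's curvature
            # invariants do not depend on the in-plane basis choice.
            r2 = u**2 + v**2
            lam = 1e-8 * (np.sum(r2**2) + 1e-12)
            D = np.diag([1.0, 0.5, 1.0, 1.0, 1.0, 1.0])
            coef = np.linalg.solve(A.T @ A + lam * D, A.T @ w)
            a, b, c, d, e, _f = coef
            denom = 1.0 + d**2 + e**2
            K = (4 * a * c - b**2) / denom**2
            H = ((1 + e**2) * 2 * a - 2 * d * e * b + (1 + d**2) * 2 * c) / (2 * denom**1.5)
            out[row, 2 * si] = -H  # outward-normal sign convention
            out[row, 2 * si + 1] = K
    if n_degenerate:
        logger.warning("%d point/scale pairs had < %d neighbors; curvature set to 0",
                       n_degenerate, min_neighbors)
    return out


# --------------------------------------------------------------------------
# quasi-geodesic convolution
# --------------------------------------------------------------------------

def quasi_geodesic_distances(points: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Pairwise quasi-geodesic distances d_ij = |x_i - x_j| (2 - <n_i, n_j>).

    The normal-alignment penalty doubles the effective distance between
    points facing opposite directions, suppressing leakage straight
    across the protein body.
    """
    euclid = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=2)
    align = normals @ normals.T
    return euclid * (2.0 - align)


class QuasiGeodesicConv(Module):
    """One surface convolution with a Gaussian quasi-geodesic window.

    Neighbor weights ``w = exp(-d^2 / (2 r^2))`` truncated at ``2r`` are
    row-normalized (each point attends at least to itself); the layer
    output is ``act(W_self f + W_nbr (w_norm @ f))``.  Weights depend on
    invariant quantities only.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, radius: float = 9.0):
        super().__init__()
        self.radius = radius
        self.w_self = Linear(in_dim, out_dim, rng)
        self.w_nbr = Linear(in_dim, out_dim, rng)

    def window(self, qg_dist: np.ndarray) -> np.ndarray:
        r = self.radius
        w = np.exp(-(qg_dist**2) / max(2 * r * r, 1e-300))
        w[qg_dist >= 2 * r] = 0.0
        np.fill_diagonal(w, 1.0)
        return w / w.sum(axis=1, keepdims=True)

    def __call__(self, feats: Tensor, qg_dist: np.ndarray) -> Tensor:
        w = self.window(qg_dist)
        neighbor = Tensor(w) @ feats
        return (self.w_self(feats) + self.w_nbr(neighbor)).relu()


class SurfaceEncoder(Module):
    """Pocket surface -> per-point scalar embeddings.

    Chemical features (learned atom-neighborhood MLP) are concatenated
    with multi-scale curvatures and passed through a stack of
    quasi-geodesic convolutions.  Every input to the network is a
    distance, a dot product of normals, or an atom type, so the final
    embedding is invariant to rigid motions of the complex.
    """

    def __init__(
        self,
        n_types: int,
        rng: np.random.Generator,
        chem_dim: int = 16,
        chem_hidden: int = 16,
        out_dim: int = 32,
        n_layers: int = 3,
        radius: float = 9.0,
        n_scales: int = len(CURVATURE_SCALES),
    ):
        super().__init__()
        self.chem = ChemicalFeatureNet(n_types, chem_dim, rng, hidden=chem_hidden)
        in_dim = chem_dim + 2 * n_scales
        dims = [in_dim] + [out_dim] * n_layers
        self.convs = [QuasiGeodesicConv(a, b, rng, radius=radius) for a, b in zip(dims[:-1], dims[1:])]

    def __call__(
        self,
        onehot: np.ndarray,
        inv_dist: np.ndarray,
        curvatures: np.ndarray,
        qg_dist: np.ndarray,
    ) -> Tensor:
        from .nn import concatenate

        chem = self.chem(onehot, inv_dist)
        feats = concatenate([chem, Tensor(curvatures)], axis=-1)
        for conv in self.convs:
            feats = conv(feats, qg_dist)
        return feats
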