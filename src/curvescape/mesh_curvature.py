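"""Per-vertex curvature of triangle meshes by local quadric fitting.

For each vertex, the vertices within a Euclidean ball of radius
r = radius_factor * <e> (with <e> the mean edge length, radius_factor 20
by default) are expressed in a local frame aligned with the
area-weighted vertex normal, and a second-order polynomial

    z = a x^2 + b x y + c y^2 + d x + e y

is fitted by least squares.  Gaussian and mean curvature follow from the
fitted fundamental forms at the origin; the linear terms absorb normal-
estimation error.  The area-normalized curvature K~ = K * A_total is a
scale-free quantity for comparing curvature spectra across shapes of
different size (e.g. a concave well versus the cell sheet spanning it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "TriMeshCurv",
    "estimate_curvature",
    "area_normalize",
    "clip_top_surface",
]


@dataclass
class TriMeshCurv:
    """Mesh with per-vertex Gaussian curvature.

    ``K``/``H`` are 1/µm^2 and 1/µm (NaN where the local fit is
    undefined); ``K_tilde`` = K * total_area is dimensionless.
    """

    mesh: trimesh.Trimesh
    K: np.ndarray
    H: np.ndarray
    mean_edge_length: float
    fit_radius: float

    @property
    def K_tilde(self) -> np.ndarray:
        return area_normalize(self.mesh, self.K)


def _validate(mesh: trimesh.Trimesh) -> None:
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise ValueError("empty mesh")
    # reject clearly broken input; open boundaries are fine (clipped tops)
    if mesh.edges_unique is None or len(mesh.edges_unique) == 0:
        raise ValueError("mesh has no edges")


def estimate_curvature(mesh: trimesh.Trimesh, radius_factor: float = 20.0,
                       min_neighbors: int = 6,
                       vertex_indices: np.ndarray | None = None,
                       max_points: int = 400, seed: int = 0) -> TriMeshCurv:
    """Estimate per-vertex K and H by local second-order polynomial fits.

    Vertices with fewer than ``min_neighbors`` neighbors in the fit ball,
    or with a rank-deficient (e.g. collinear) neighborhood, are flagged
    NaN rather than extrapolated.

    ``vertex_indices`` restricts evaluation to a subset of vertices (K/H
    stay NaN elsewhere), and neighborhoods larger than ``max_points`` are
    subsampled (seeded) before the fit; both keep dense meshes tractable
    without changing the estimator's locality.
    """
    if radius_factor <= 0:
        raise ValueError("radius_factor must be positive")
    _validate(mesh)
    V = np.asarray(mesh.vertices, float)
    normals = np.asarray(mesh.vertex_normals, float)
    edges = V[mesh.edges_unique]
    e_mean = float(np.linalg.norm(edges[:, 0] - edges[:, 1], axis=1).mean())
    r = radius_factor * e_mean

    tree = cKDTree(V)
    K = np.full(len(V), np.nan)
    H = np.full(len(V), np.nan)
    if vertex_indices is None:
        vertex_indices = np.arange(len(V))
    vertex_indices = np.asarray(vertex_indices, int)
    rng = np.random.default_rng(seed)
    neighborhoods = tree.query_ball_point(V[vertex_indices], r)
    for i, idx in zip(vertex_indices, neighborhoods):
        idx = np.asarray(idx)
        if idx.size < min_neighbors + 1:
            continue
        if idx.size > max_points:
            idx = rng.choice(idx, max_points, replace=False)
        n = normals[i]
        # local orthonormal frame (t1, t2, n)
        a = np.array([1.0, 0.0, 0.0])
        if abs(n[0]) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        t1 = np.cross(n, a)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(n, t1)
        rel = V[idx] - V[i]
        x = rel @ t1
        y = rel @ t2
        z = rel @ n
        A = np.column_stack([x * x, x * y, y * y, x, y])
        coef, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
        if rank < 5:
            continue
        fa, fb, fc, fd, fe = coef
        # fundamental forms of z = f(x, y) at the origin with grad (fd, fe)
        den = 1.0 + fd * fd + fe * fe
        sq = np.sqrt(den)
        E, F, G = 1.0 + fd * fd, fd * fe, 1.0 + fe * fe
        L, M, N = 2.0 * fa / sq, fb / sq, 2.0 * fc / sq
        K[i] = (L * N - M * M) / (E * G - F * F)
        H[i] = (E * N + G * L - 2.0 * F * M) / (2.0 * (E * G - F * F))
    return TriMeshCurv(mesh, K, H, e_mean, r)


def area_normalize(mesh: trimesh.Trimesh, K: np.ndarray) -> np.ndarray:
    """Dimensionless K~ = K * total surface area (invariant to scaling)."""
    A = float(mesh.area)
    if A <= 0:
        raise ValueError("mesh has non-positive area")
    return np.asarray(K, float) * A


def clip_top_surface(mesh: trimesh.Trimesh, plane_z: float) -> trimesh.Trimesh:
    """Keep the faces lying entirely above a horizontal plane.

    Returns an open mesh of the top side; clipping below the lowest
    vertex is the identity, clipping above the highest is an error.
    """
    _validate(mesh)
    V = np.asarray(mesh.vertices)
    above = V[:, 2] > plane_z
    face_keep = above[mesh.faces].all(axis=1)
    if not face_keep.any():
        raise ValueError("clip plane above the whole mesh: empty result")
    out = mesh.submesh([np.flatnonzero(face_keep)], append=True)
    return out
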