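import numpy as np
import pytest

from curvescape.surface_geometry import SubstrateSpec, make_patch
from curvescape.projection_maps import (
    CurvatureMapStack, add_transition_band, distance_map, project_topview)


def fd_fundamental_forms(xyz):
    """Finite-difference first/second fundamental forms of a sampled patch.

    Independent oracle for the analytic curvatures: central differences on
    the (u, v) grid of positions, normal from Xu x Xv.  Returns (H, K)
    with the sign of H tied to the FD normal orientation (compare |H|).
    """
    Xu = np.gradient(xyz, axis=0)
    Xv = np.gradient(xyz, axis=1)
    n = np.cross(Xu, Xv)
    with np.errstate(invalid="ignore", divide="ignore"):
        n /= np.linalg.norm(n, axis=-1, keepdims=True)
    Xuu = np.gradient(Xu, axis=0)
    Xuv = np.gradient(Xu, axis=1)
    Xvv = np.gradient(Xv, axis=1)
    E = (Xu * Xu).sum(-1)
    F = (Xu * Xv).sum(-1)
    G = (Xv * Xv).sum(-1)
    L = (Xuu * n).sum(-1)
    M = (Xuv * n).sum(-1)
    N = (Xvv * n).sum(-1)
    den = E * G - F * F
    K = (L * N - M * M) / den
    H = (E * N + G * L - 2 * F * M) / (2 * den)
    return H, K


@pytest.fixture(scope="session")
def sphere_spec():
    return SubstrateSpec("spheres", n_periods=1)


@pytest.fixture(scope="session")
def sphere_stack(sphere_spec):
    """Convex 180 µm sphere projected at 2 µm pixels (coarse but exact)."""
    patch = make_patch(sphere_spec, n_samples=900, n_angles=900)
    return project_topview(patch, pixel_size=2.0,
                           norm_radius=sphere_spec.sphere_radius, margin=30.0)


@pytest.fixture(scope="session")
def sphere_stack_banded(sphere_stack):
    return add_transition_band(sphere_stack, 15.0, "convex")


@pytest.fixture(scope="session")
def sphere_dmap(sphere_stack_banded):
    return distance_map(sphere_stack_banded)


def toy_stack(kappa2_row, pixel_size=1.0):
    """Single-row curvature stack from a list of kappa2 values."""
    k2 = np.asarray(kappa2_row, float)[None, :]
    k1 = np.maximum(k2, 0.0)
    return CurvatureMapStack(
        pixel_size=pixel_size, norm_radius=180.0,
        kappa1=np.maximum(k1, k2), kappa2=np.minimum(k1, k2),
        pd_angle=np.full_like(k2, np.nan),
        footprint=np.ones_like(k2, bool),
        undefined_dir=np.ones_like(k2, bool))
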