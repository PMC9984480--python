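"""Parametric substrate surfaces with exact differential geometry.

Six surface families are used as cell-culture substrate designs: a plain
cylinder, a string of spheres, an unduloid (the constant-mean-curvature
Delaunay surface interpolating between the two), strings of catenoids
(minimal, H = 0) and pseudospheres (constant negative K), and a cylinder
swept along a sinusoidal path (alternating-K tube).  Every surface is a
half-surface (a pi-revolution, or half-tube) standing on the planar
substrate, and every sample carries closed-form principal curvatures.

Sign convention: the surface normal points away from the solid (upwards,
out of the substrate), and curvature is positive where the surface bulges
towards the normal.  A spherical protrusion of radius R therefore has
kappa1 = kappa2 = +1/R and a spherical well -1/R.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "SubstrateSpec",
    "Generatrix",
    "ParamPatch",
    "FAMILIES",
    "make_generatrix",
    "revolve",
    "sweep_sinusoid",
    "apply_convexity",
    "scale_substrate",
    "normalize_curvature",
    "make_patch",
]

FAMILIES = (
    "cylinder",
    "unduloid",
    "spheres",
    "catenoids",
    "pseudospheres",
    "sinusoidal_cylinder",
)

AXISYMMETRIC = FAMILIES[:5]

#: tolerance below which |kappa1 - kappa2| marks an umbilic sample
UMBILIC_TOL = 1e-9


@dataclass(frozen=True)
class SubstrateSpec:
    """Parametric definition of one substrate design.

    ``scale`` multiplies every length of the design (0.5, 1.0 and 2.0 are
    the 50/100/200% variants); curvatures divide by it.  The spherical
    substrate of the design has radius ``base_sphere_radius * scale``,
    which is also the normalization length for dimensionless curvature.
    """

    family: str
    convexity: str = "convex"
    scale: float = 1.0
    base_sphere_radius: float = 180.0  # µm
    n_periods: int = 3
    param_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.convexity not in ("convex", "concave"):
            raise ValueError(f"convexity must be convex/concave, got {self.convexity!r}")
        if self.scale <= 0 or self.base_sphere_radius <= 0:
            raise ValueError("scale and base_sphere_radius must be positive")
        if self.n_periods < 1:
            raise ValueError("n_periods must be >= 1")

    @property
    def sphere_radius(self) -> float:
        """Radius (µm) of the spherical design at this scale."""
        return self.base_sphere_radius * self.scale

    def shape_params(self) -> dict:
        """Family shape parameters in µm at this spec's scale.

        Defaults are reconstructions chosen so that cylinder, unduloid and
        spheres share the same constant mean curvature H = 1/(2R) with
        R the sphere radius, and so the saddle families sit at comparable
        cell-scale dimensions.
        """
        R = self.sphere_radius
        p: dict = {}
        if self.family == "cylinder":
            # constant-H family: H_cyl = 1/(2 r) = H_sph = 1/(2R) -> r = R/2
            p["radius"] = R / 2.0
        elif self.family == "spheres":
            p["radius"] = R
        elif self.family == "unduloid":
            # H = 1/(bulge+neck) must equal the sphere's H = 1/R
            p["bulge_radius"] = 0.75 * R
            p["neck_radius"] = 0.25 * R
        elif self.family == "catenoids":
            p["neck_radius"] = R / 3.0
            p["rim_radius"] = R
        elif self.family == "pseudospheres":
            p["c"] = R / 2.0
            p["cusp_radius"] = R / 6.0
            # the tractroid rim (theta = 90 deg) is a cuspidal edge with
            # unbounded meridian curvature; truncate just below it
            p["rim_angle_deg"] = 87.0
        elif self.family == "sinusoidal_cylinder":
            p["tube_radius"] = R / 2.0
            p["amplitude"] = 80.0 * self.scale
            p["wavelength"] = 720.0 * self.scale
        p.update(self.param_overrides)
        return p


@dataclass
class Generatrix:
    """Sampled profile curve of a surface of revolution.

    ``axial``/``radial`` are positions (µm); the d*/dd* arrays are exact
    first and second derivatives with respect to the parameter ``t``, so
    the revolved surface's fundamental forms are closed-form, not
    finite-differenced.  ``pinch`` flags samples where the profile touches
    the axis (radial ~ 0), e.g. where consecutive spheres meet.
    """

    t: np.ndarray
    axial: np.ndarray
    radial: np.ndarray
    d_axial: np.ndarray
    d_radial: np.ndarray
    dd_axial: np.ndarray
    dd_radial: np.ndarray
    pinch: np.ndarray

    def __post_init__(self):
        if np.any(self.radial < -1e-9):
            raise ValueError("generatrix radial coordinate must be >= 0")


@dataclass
class ParamPatch:
    """Sampled surface patch with per-sample differential geometry.

    Arrays are (nu, nv[, 3]); curvatures are in 1/µm with kappa1 >= kappa2.
    ``pd1``/``pd2`` are unit tangents along the principal directions of
    kappa1 and kappa2; at umbilic samples (kappa1 == kappa2) the directions
    are degenerate and ``umbilic`` is set (directions there are NaN).
    ``flagged`` marks samples on axis pinches or other degeneracies.
    """

    u_grid: np.ndarray
    v_grid: np.ndarray
    xyz: np.ndarray
    normal: np.ndarray
    kappa1: np.ndarray
    kappa2: np.ndarray
    pd1: np.ndarray
    pd2: np.ndarray
    umbilic: np.ndarray
    flagged: np.ndarray

    @property
    def H(self) -> np.ndarray:
        """Mean curvature H = (kappa1 + kappa2) / 2 (1/µm)."""
        return 0.5 * (self.kappa1 + self.kappa2)

    @property
    def K(self) -> np.ndarray:
        """Gaussian curvature K = kappa1 * kappa2 (1/µm^2)."""
        return self.kappa1 * self.kappa2


# ----------------------------------------------------------------------
# generatrix construction


def _tile_periods(t, ax, r, da, dr, dda, ddr, period_len, n_periods, mirror):
    """Concatenate one period of a profile into a string of n_periods.

    If ``mirror`` is true, odd repeats are mirrored in the axial direction
    (C0 joins); otherwise periods are translated copies.
    """
    ts, axs, rs, das, drs, ddas, ddrs = [], [], [], [], [], [], []
    t_span = t[-1] - t[0]
    for k in range(n_periods):
        off = k * period_len
        if mirror and (k % 2 == 1):
            axs.append(off + period_len - (ax[::-1] - ax[0]) - 0.0)
            # mirrored copy: axial reflected, derivative signs flip
            axs[-1] = off + (ax[-1] - ax[::-1])
            rs.append(r[::-1])
            das.append(da[::-1])
            drs.append(-dr[::-1])
            ddas.append(-dda[::-1])
            ddrs.append(ddr[::-1])
        else:
            axs.append(ax - ax[0] + off)
            rs.append(r)
            das.append(da)
            drs.append(dr)
            ddas.append(dda)
            ddrs.append(ddr)
        ts.append(t - t[0] + k * t_span)
    cat = lambda xs: np.concatenate(xs)
    return cat(ts), cat(axs), cat(rs), cat(das), cat(drs), cat(ddas), cat(ddrs)


def make_generatrix(spec: SubstrateSpec, n_samples: int = 256) -> Generatrix:
    """Sample the profile curve of an axisymmetric substrate.

    Returns per-period samples of the (axial, radial) profile with exact
    parameter derivatives, covering ``spec.n_periods`` periods.
    ``n_samples`` is the number of samples per period.
    """
    if spec.family == "sinusoidal_cylinder":
        raise ValueError("sinusoidal_cylinder is not axisymmetric; use sweep_sinusoid")
    if spec.family not in AXISYMMETRIC:
        raise ValueError(f"unknown axisymmetric family {spec.family!r}")
    if n_samples < 16:
        raise ValueError("n_samples must be >= 16")
    p = spec.shape_params()
    n = int(n_samples)

    if spec.family == "cylinder":
        R = p["radius"]
        if R <= 0:
            raise ValueError("cylinder radius must be positive")
        period = 2.0 * spec.sphere_radius  # nominal unit length along axis
        t = np.linspace(0.0, period, n)
        ax, r = t.copy(), np.full(n, R)
        da, dr = np.ones(n), np.zeros(n)
        dda = ddr = np.zeros(n)
        t, ax, r, da, dr, dda, ddr = _tile_periods(
            t, ax, r, da, dr, dda, ddr, period, spec.n_periods, mirror=False)
        pinch = np.zeros_like(r, bool)

    elif spec.family == "spheres":
        R = p["radius"]
        if R <= 0:
            raise ValueError("sphere radius must be positive")
        t = np.linspace(0.0, np.pi, n)
        ax = R - R * np.cos(t)
        r = R * np.sin(t)
        da, dr = R * np.sin(t), R * np.cos(t)
        dda, ddr = R * np.cos(t), -R * np.sin(t)
        t, ax, r, da, dr, dda, ddr = _tile_periods(
            t, ax, r, da, dr, dda, ddr, 2.0 * R, spec.n_periods, mirror=False)
        pinch = r < 1e-9 * R

    elif spec.family == "unduloid":
        a_b, b_n = p["bulge_radius"], p["neck_radius"]
        if not (a_b > b_n > 0):
            raise ValueError("unduloid needs bulge_radius > neck_radius > 0")
        D = a_b**2 - b_n**2
        t = np.linspace(0.0, np.pi, n)
        r = np.sqrt(a_b**2 * np.sin(t) ** 2 + b_n**2 * np.cos(t) ** 2)
        dr = 0.5 * D * np.sin(2 * t) / r
        ddr = D * np.cos(2 * t) / r - dr**2 / r
        da = (a_b * b_n + r**2) / r          # dz/dt, from the CMC first integral
        dda = dr * (1.0 - a_b * b_n / r**2)
        ax = cumulative_trapezoid(da, t, initial=0.0)
        # refine quadrature: dense Simpson on a fine grid, sampled back
        tf = np.linspace(0.0, np.pi, 20 * n + 1)
        rf = np.sqrt(a_b**2 * np.sin(tf) ** 2 + b_n**2 * np.cos(tf) ** 2)
        daf = (a_b * b_n + rf**2) / rf
        axf = cumulative_trapezoid(daf, tf, initial=0.0)
        ax = np.interp(t, tf, axf)
        period = axf[-1]
        t, ax, r, da, dr, dda, ddr = _tile_periods(
            t, ax, r, da, dr, dda, ddr, period, spec.n_periods, mirror=False)
        pinch = np.zeros_like(r, bool)

    elif spec.family == "catenoids":
        c, Rr = p["neck_radius"], p["rim_radius"]
        if not (Rr > c > 0):
            raise ValueError("catenoids need rim_radius > neck_radius > 0")
        L = c * np.arccosh(Rr / c)
        t = np.linspace(-L, L, n)
        ax = t - (-L)
        r = c * np.cosh(t / c)
        da = np.ones(n)
        dr = np.sinh(t / c)
        dda = np.zeros(n)
        ddr = np.cosh(t / c) / c
        t, ax, r, da, dr, dda, ddr = _tile_periods(
            t, ax, r, da, dr, dda, ddr, 2.0 * L, spec.n_periods, mirror=False)
        pinch = np.zeros_like(r, bool)

    elif spec.family == "pseudospheres":
        c = p["c"]
        r_cut = p["cusp_radius"]
        if not (c > r_cut > 0):
            raise ValueError("pseudospheres need c > cusp_radius > 0")
        th_min = np.arcsin(r_cut / c)
        th_max = np.deg2rad(p.get("rim_angle_deg", 87.0))
        if not (th_min < th_max <= 0.5 * np.pi):
            raise ValueError("pseudosphere rim angle out of range")
        # half period: truncated cusp up to (just below) the rim
        th = np.linspace(th_min, th_max, n // 2 + 1)
        ax_h = c * (np.cos(th) + np.log(np.tan(0.5 * th)))
        r_h = c * np.sin(th)
        da_h = c * np.cos(th) ** 2 / np.sin(th)
        dr_h = c * np.cos(th)
        dda_h = -c * np.cos(th) * (1 + np.sin(th) ** 2) / np.sin(th) ** 2
        ddr_h = -c * np.sin(th)
        # one full period: cusp -> rim -> cusp (mirror about the rim)
        half = len(th)
        t1 = th
        t = np.concatenate([t1, t1[-2::-1] + (t1[-1] - t1[0]) + (t1[-1] - t1[-2])])
        z0 = ax_h[0]
        ax = np.concatenate([ax_h - z0, (ax_h[-1] - z0) + (ax_h[-1] - ax_h[-2::-1])])
        r = np.concatenate([r_h, r_h[-2::-1]])
        da = np.concatenate([da_h, da_h[-2::-1]])
        dr = np.concatenate([dr_h, -dr_h[-2::-1]])
        dda = np.concatenate([dda_h, -dda_h[-2::-1]])
        ddr = np.concatenate([ddr_h, ddr_h[-2::-1]])
        t = np.arange(len(ax), dtype=float)  # mirror breaks the theta param; reindex
        period = ax[-1]
        t, ax, r, da, dr, dda, ddr = _tile_periods(
            t, ax, r, da, dr, dda, ddr, period, spec.n_periods, mirror=False)
        pinch = np.zeros_like(r, bool)

    return Generatrix(t, ax, r, da, dr, dda, ddr, pinch)


# ----------------------------------------------------------------------
# revolution and sweeping


def revolve(gen: Generatrix, n_angles: int = 181) -> ParamPatch:
    """Revolve a generatrix by pi about its axis (a half-surface).

    The axis of revolution lies along y in the substrate plane; the patch
    occupies z >= 0.  Meridians and parallels are the principal directions;
    their curvatures come from the surface-of-revolution closed forms

        kappa_m = (a'' r' - a' r'') / (a'^2 + r'^2)^(3/2)
        kappa_p = a' / (r * sqrt(a'^2 + r'^2))

    with (a, r) the axial/radial profile, primes denoting d/dt.  Samples
    with r = 0 (axis pinch) are flagged, not silently NaN.
    """
    phi = np.linspace(0.0, np.pi, n_angles)
    a, r = gen.axial, gen.radial
    da, dr, dda, ddr = gen.d_axial, gen.d_radial, gen.dd_axial, gen.dd_radial
    sp = np.hypot(da, dr)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa_m = (dda * dr - da * ddr) / sp**3
        kappa_p = da / (r * sp)
    flagged = gen.pinch | ~np.isfinite(kappa_m) | ~np.isfinite(kappa_p)
    kappa_m = np.where(flagged, 0.0, kappa_m)
    kappa_p = np.where(flagged, 0.0, kappa_p)

    cphi, sphi = np.cos(phi), np.sin(phi)
    # grids (nu, nv)
    X = r[:, None] * cphi[None, :]
    Y = np.broadcast_to(a[:, None], (len(a), len(phi))).copy()
    Z = r[:, None] * sphi[None, :]
    xyz = np.stack([X, Y, Z], axis=-1)

    # outward normal (a' cos, -r', a' sin)/s'
    nx = (da / sp)[:, None] * cphi[None, :]
    ny = np.broadcast_to((-dr / sp)[:, None], X.shape)
    nz = (da / sp)[:, None] * sphi[None, :]
    normal = np.stack([nx, ny, nz], axis=-1)

    # meridian tangent (r' cos, a', r' sin)/s'; parallel tangent (-sin, 0, cos)
    em = np.stack([
        (dr / sp)[:, None] * cphi[None, :],
        np.broadcast_to((da / sp)[:, None], X.shape),
        (dr / sp)[:, None] * sphi[None, :],
    ], axis=-1)
    ep = np.stack([
        np.broadcast_to(-sphi[None, :], X.shape),
        np.zeros_like(X),
        np.broadcast_to(cphi[None, :], X.shape),
    ], axis=-1)

    km = np.broadcast_to(kappa_m[:, None], X.shape)
    kp = np.broadcast_to(kappa_p[:, None], X.shape)
    return _assemble_patch(gen.t, phi, xyz, normal, km, kp, em, ep,
                           np.broadcast_to(flagged[:, None], X.shape))


def sweep_sinusoid(circle_radius: float, amplitude: float, wavelength: float,
                   n_periods: int = 3, n_s: int = 512, n_angles: int = 181,
                   ) -> ParamPatch:
    """Half-tube swept along a sinusoidal path in the substrate plane.

    The path is x = A sin(2 pi y / wavelength) running along y; the tube
    cross-section is a half-circle of ``circle_radius`` above the plane.
    Principal curvatures follow the tube-around-a-curve closed form: 1/r
    around the cross-section and -k cos(phi) / (1 - r k cos(phi)) along
    the path, with k the signed path curvature and phi the tube angle from
    the in-plane path normal.  K alternates sign along each bend and
    vanishes on the crest above path inflections.
    """
    r0, A, lam = float(circle_radius), float(amplitude), float(wavelength)
    if r0 <= 0 or lam <= 0 or A < 0:
        raise ValueError("non-positive tube dimensions")
    w = 2.0 * np.pi / lam
    kmax = A * w**2
    if kmax * r0 >= 1.0:
        raise ValueError("self-intersecting sweep: amplitude * (2*pi/wavelength)^2 "
                         "must be < 1/circle_radius")
    s = np.linspace(0.0, n_periods * lam, int(n_s) * n_periods)
    phi = np.linspace(0.0, np.pi, n_angles)
    x, y = A * np.sin(w * s), s
    dx, dy = A * w * np.cos(w * s), np.ones_like(s)
    ddx, ddy = -A * w**2 * np.sin(w * s), np.zeros_like(s)
    v = np.hypot(dx, dy)
    k = (dx * ddy - dy * ddx) / v**3     # signed planar curvature
    T = np.stack([dx / v, dy / v, np.zeros_like(s)], axis=-1)
    N = np.stack([-dy / v, dx / v, np.zeros_like(s)], axis=-1)  # left normal
    zhat = np.array([0.0, 0.0, 1.0])

    cphi, sphi = np.cos(phi), np.sin(phi)
    gamma = np.stack([x, y, np.zeros_like(s)], axis=-1)
    xyz = (gamma[:, None, :] + r0 * cphi[None, :, None] * N[:, None, :]
           + r0 * sphi[None, :, None] * zhat)
    normal = cphi[None, :, None] * N[:, None, :] + sphi[None, :, None] * zhat
    normal = np.broadcast_to(normal, xyz.shape).copy()

    f = 1.0 - r0 * k[:, None] * cphi[None, :]
    k_long = -k[:, None] * cphi[None, :] / f
    k_circ = np.full_like(k_long, 1.0 / r0)
    e_long = np.broadcast_to(T[:, None, :], xyz.shape).copy()
    e_circ = (-sphi[None, :, None] * N[:, None, :]
              + cphi[None, :, None] * np.broadcast_to(zhat, N[:, None, :].shape))
    e_circ = np.broadcast_to(e_circ, xyz.shape).copy()
    flagged = np.zeros(k_long.shape, bool)
    return _assemble_patch(s, phi, xyz, normal, k_long, k_circ,
                           e_long, e_circ, flagged)


def _assemble_patch(u, v, xyz, normal, ka, kb, ea, eb, flagged) -> ParamPatch:
    """Sort the two principal curvature channels into kappa1 >= kappa2."""
    ka = np.asarray(ka, float).copy()
    kb = np.asarray(kb, float).copy()
    swap = kb > ka
    k1 = np.where(swap, kb, ka)
    k2 = np.where(swap, ka, kb)
    pd1 = np.where(swap[..., None], eb, ea)
    pd2 = np.where(swap[..., None], ea, eb)
    umb = np.abs(k1 - k2) < UMBILIC_TOL * np.maximum(
        1.0, np.maximum(np.abs(k1), np.abs(k2)))
    pd1 = pd1.copy()
    pd2 = pd2.copy()
    pd1[umb] = np.nan
    pd2[umb] = np.nan
    return ParamPatch(np.asarray(u), np.asarray(v), xyz, normal,
                      k1, k2, pd1, pd2, umb, flagged)


# ----------------------------------------------------------------------
# transforms


def apply_convexity(patch: ParamPatch, convexity: str) -> ParamPatch:
    """Return the convex or concave variant of a patch.

    The concave (imprint) variant negates both principal curvatures, which
    flips the sign of H, leaves K unchanged, and exchanges the principal
    directions: kappa1 <- -kappa2, kappa2 <- -kappa1.  Applying the
    transform twice is the identity.
    """
    if convexity == "convex":
        return patch
    if convexity != "concave":
        raise ValueError(f"convexity must be convex/concave, got {convexity!r}")
    xyz = patch.xyz.copy()
    xyz[..., 2] = -xyz[..., 2]            # imprint: geometry mirrored in z
    return ParamPatch(
        patch.u_grid, patch.v_grid, xyz, -patch.normal,
        -patch.kappa2.copy(), -patch.kappa1.copy(),
        patch.pd2.copy(), patch.pd1.copy(),
        patch.umbilic.copy(), patch.flagged.copy())


def scale_substrate(spec: SubstrateSpec, factor: float) -> SubstrateSpec:
    """Uniformly scale a design: lengths multiply by ``factor``."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return replace(spec, scale=spec.scale * factor)


def normalize_curvature(kappa, spec: SubstrateSpec):
    """Non-dimensionalize curvature by the design's sphere radius.

    Multiplies by ``base_sphere_radius * scale``, so the convex spherical
    substrate has normalized kappa1 = kappa2 = 1.
    """
    return np.asarray(kappa, float) * spec.sphere_radius


def make_patch(spec: SubstrateSpec, n_samples: int = 256,
               n_angles: int = 181) -> ParamPatch:
    """Build the sampled half-surface patch for any family of a spec."""
    if spec.family == "sinusoidal_cylinder":
        p = spec.shape_params()
        patch = sweep_sinusoid(p["tube_radius"], p["amplitude"], p["wavelength"],
                               n_periods=spec.n_periods, n_s=n_samples,
                               n_angles=n_angles)
    else:
        patch = revolve(make_generatrix(spec, n_samples), n_angles)
    return apply_convexity(patch, spec.convexity)
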