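"""Ground-truthed synthetic fluorescence data for the whole pipeline.

Raw confocal data for this kind of experiment are rarely deposited, so
every pipeline stage is exercised on synthetic inputs with known ground
truth: actin-like oriented fiber textures whose mean intensity decays
with the distance map (decay length lambda_I), DAPI-like ellipse nuclei
sampled from a density proportional to exp(-delta/lambda_n), z-stacks
containing a suspended sheet with a planted sag over a concave well plus
cylindrical anchor bridges, and triangle meshes of shapes with
closed-form Gaussian curvature.

All generators are deterministic given (truth, seed): a single scene
seed is combined with a fixed per-operation offset through numpy's
SeedSequence, so adding a generator never perturbs existing scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage

from .nuclei_quant import NucleiSet

__all__ = [
    "SceneTruth",
    "synth_actin_image",
    "synth_nuclei_image",
    "synth_sheet_stack",
    "synth_mesh",
    "striped_tile",
]

# fixed substream offsets per operation
_STREAM_ACTIN = 1
_STREAM_NUCLEI = 2
_STREAM_SHEET = 3


@dataclass
class SceneTruth:
    """Planted parameters of one synthetic scene.

    Lengths in µm; the default image geometry (1024 x 1024 px at
    0.60 µm/px) matches the confocal acquisition scale of the study
    design.  ``noise_sigma`` is Gaussian read noise on a unit-intensity
    scale and ``poisson_gain`` the photons-per-unit-intensity of the shot
    noise (0 disables it).
    """

    seed: int = 0
    pixel_size: float = 0.60
    shape: tuple = (1024, 1024)
    # actin texture
    lambda_I: float = 40.0          # intensity decay length vs delta, µm
    intensity_contrast: float = 1.5  # 'a' in base * (1 + a exp(-delta/lambda))
    fiber_length: float = 30.0      # µm
    fiber_width: float = 1.2        # µm
    fiber_density: float = 0.02     # fibers per µm^2
    angle_jitter: float = 5.0       # degrees around the planted field
    # nuclei
    lambda_n: float = 40.0          # nucleus density decay length, µm
    n_nuclei: int = 400
    nucleus_axes: tuple = (8.0, 14.0)   # full-axis range, µm
    # sheet stack
    sag: float = 40.0               # µm
    well_radius: float = 180.0      # µm (concave hemispherical well)
    anchors: tuple = ()             # ((x µm, y µm, radius µm), ...)
    voxel_z: float = 2.0            # µm
    # noise
    noise_sigma: float = 0.05
    poisson_gain: float = 50.0

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), int(stream)]))


def _add_noise(img: np.ndarray, rng: np.random.Generator,
               sigma: float, gain: float) -> np.ndarray:
    out = np.clip(img, 0, None)
    if gain > 0:
        out = rng.poisson(out * gain) / gain
    if sigma > 0:
        out = out + rng.normal(0.0, sigma, size=out.shape)
    return np.clip(out, 0, None)


def striped_tile(size: int, angle_deg: float, period: float = 8.0,
                 snr: float = np.inf, seed: int = 0,
                 phase: float = 0.0) -> np.ndarray:
    """Sinusoidal stripe tile at a given orientation, for calibration.

    The stripes run *along* ``angle_deg`` (measured from the image
    horizontal, counterclockwise in array coordinates); intensity varies
    across them with the given ``period`` in pixels.  Finite ``snr`` adds
    white Gaussian noise with amplitude std(signal)/snr.
    """
    y, x = np.mgrid[0:size, 0:size].astype(float)
    th = np.radians(angle_deg)
    # wave vector perpendicular to the stripe direction
    proj = -x * np.sin(th) + y * np.cos(th)
    img = 1.0 + np.sin(2 * np.pi * proj / period + phase)
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, img.std() / snr, size=img.shape)
    return img


def _draw_filaments(shape, rng, centers, angles, length_px, width_px):
    """Accumulate Gaussian-profile line segments into an image."""
    img = np.zeros(shape)
    half = length_px / 2.0
    pad = int(np.ceil(half + 4 * width_px))
    ny, nx = shape
    for (cy, cx), ang in zip(centers, angles):
        th = np.radians(ang)
        ux, uy = np.cos(th), np.sin(th)
        y0, y1 = int(max(0, cy - pad)), int(min(ny, cy + pad + 1))
        x0, x1 = int(max(0, cx - pad)), int(min(nx, cx + pad + 1))
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
        dx, dy = xx - cx, yy - cy
        along = dx * ux + dy * uy
        perp = -dx * uy + dy * ux
        prof = np.exp(-0.5 * (perp / width_px) ** 2)
        cap = 1.0 / (1.0 + np.exp((np.abs(along) - half) / max(width_px, 1.0)))
        img[y0:y1, x0:x1] += prof * cap
    return img


def synth_actin_image(truth: SceneTruth, delta: np.ndarray | None = None,
                      angle_field: np.ndarray | None = None,
                      superpixel: int = 80,
                      base_intensity: float = 1.0) -> np.ndarray:
    """Oriented fiber texture with distance-modulated mean intensity.

    ``angle_field`` holds one planted fiber angle (degrees) per
    ``superpixel`` tile (NaN tiles get random angles); fibers are placed
    uniformly with density ``truth.fiber_density`` and angle jitter
    ``truth.angle_jitter``.  If ``delta`` (µm raster, image-shaped) is
    given, the local mean is modulated by
    base * (1 + a * exp(-delta / lambda_I)); a = 0 gives a statistically
    flat image.  Poisson + Gaussian noise is applied last.
    """
    rng = truth.rng(_STREAM_ACTIN)
    ny, nx = truth.shape
    px = truth.pixel_size
    n_fibers = rng.poisson(truth.fiber_density * (ny * px) * (nx * px))
    centers = np.column_stack([rng.uniform(0, ny, n_fibers),
                               rng.uniform(0, nx, n_fibers)])
    if angle_field is None:
        angles = rng.uniform(0, 180, n_fibers)
    else:
        af = np.asarray(angle_field, float)
        ti = np.minimum((centers[:, 0] // superpixel).astype(int), af.shape[0] - 1)
        tj = np.minimum((centers[:, 1] // superpixel).astype(int), af.shape[1] - 1)
        angles = af[ti, tj]
        undef = ~np.isfinite(angles)
        angles[undef] = rng.uniform(0, 180, undef.sum())
        angles = angles + rng.normal(0, truth.angle_jitter, n_fibers)
    img = _draw_filaments((ny, nx), rng, centers, angles,
                          truth.fiber_length / px, truth.fiber_width / px)
    img = base_intensity * (0.1 + img)
    if delta is not None:
        delta = np.asarray(delta, float)
        if delta.shape != (ny, nx):
            raise ValueError("delta raster must match the image shape")
        img = img * (1.0 + truth.intensity_contrast
                     * np.exp(-delta / truth.lambda_I))
    return _add_noise(img, rng, truth.noise_sigma * base_intensity,
                      truth.poisson_gain)


def synth_nuclei_image(truth: SceneTruth, delta: np.ndarray | None = None,
                       min_separation: float = 0.0, render: bool = True,
                       ) -> tuple[np.ndarray | None, NucleiSet]:
    """DAPI-like ellipse nuclei sampled from exp(-delta/lambda_n).

    Nuclei are placed by rejection sampling from the density field
    rho(x) proportional to exp(-delta / lambda_n) (uniform when ``delta``
    is None or lambda_n is inf), rendered as rotated filled ellipses with
    full axes drawn from ``truth.nucleus_axes``, blurred and noised.
    ``min_separation`` (µm) optionally enforces non-overlapping nuclei.
    Returns (image, ground-truth NucleiSet in µm); with ``render=False``
    the image is None and only the sampled truth is returned (areas then
    come from the drawn axes without rasterization).
    """
    rng = truth.rng(_STREAM_NUCLEI)
    ny, nx = truth.shape
    px = truth.pixel_size

    if delta is not None:
        delta = np.asarray(delta, float)
        if delta.shape != (ny, nx):
            raise ValueError("delta raster must match the image shape")

    centers = []
    tries = 0
    max_tries = 200 * truth.n_nuclei + 1000
    while len(centers) < truth.n_nuclei and tries < max_tries:
        tries += 1
        cy = rng.uniform(0, ny)
        cx = rng.uniform(0, nx)
        if delta is not None and np.isfinite(truth.lambda_n):
            p = np.exp(-delta[int(cy), int(cx)] / truth.lambda_n)
            if rng.uniform() > p:
                continue
        if min_separation > 0 and centers:
            d2 = [(cy - a) ** 2 + (cx - b) ** 2 for a, b in centers]
            if min(d2) < (min_separation / px) ** 2:
                continue
        centers.append((cy, cx))
    centers = np.asarray(centers, float).reshape(-1, 2)

    img = np.zeros((ny, nx)) if render else None
    areas = []
    lo, hi = truth.nucleus_axes
    yy0, xx0 = np.mgrid[-40:41, -40:41].astype(float)
    for cy, cx in centers:
        amaj = rng.uniform(lo, hi) / 2.0 / px     # semi-axes, px
        amin = rng.uniform(lo, amaj * 2 * px) / 2.0 / px
        amin = min(amin, amaj)
        th = rng.uniform(0, np.pi)
        areas.append(np.pi * amaj * amin * px * px)
        if not render:
            continue
        ca, sa = np.cos(th), np.sin(th)
        u = (xx0 * ca + yy0 * sa) / amaj
        v = (-xx0 * sa + yy0 * ca) / amin
        ell = (u * u + v * v) <= 1.0
        y0, x0 = int(round(cy)) - 40, int(round(cx)) - 40
        ys = slice(max(0, y0), min(ny, y0 + 81))
        xs = slice(max(0, x0), min(nx, x0 + 81))
        eys = slice(ys.start - y0, ys.stop - y0)
        exs = slice(xs.start - x0, xs.stop - x0)
        img[ys, xs] += ell[eys, exs].astype(float)
    if render:
        img = np.clip(img, 0, 1)
        img = ndimage.gaussian_filter(img, 1.0)
        img = _add_noise(img, rng, truth.noise_sigma, truth.poisson_gain)

    xy_um = np.stack([centers[:, 1] * px, centers[:, 0] * px], axis=1)
    return img, NucleiSet(xy_um, np.asarray(areas), source="synthetic")


def well_substrate_height(truth: SceneTruth, x_um: np.ndarray,
                          y_um: np.ndarray, stack_height: float) -> np.ndarray:
    """Height (µm above stack bottom) of the concave well surface.

    The well is a hemispherical imprint of radius ``truth.well_radius``
    centered in the field; the plane sits at ``stack_height`` minus one
    shell thickness.
    """
    R = truth.well_radius
    ny, nx = truth.shape
    cx = nx * truth.pixel_size / 2.0
    cy = ny * truth.pixel_size / 2.0
    rho2 = (np.asarray(x_um) - cx) ** 2 + (np.asarray(y_um) - cy) ** 2
    h_plane = stack_height
    inside = rho2 < R * R
    h = np.where(inside, h_plane - np.sqrt(np.clip(R * R - rho2, 0, None)),
                 h_plane)
    return h


def synth_sheet_stack(truth: SceneTruth, shell: float = 3.0,
                      background: float = 0.02) -> np.ndarray:
    """Actin z-stack of a suspended sheet over a concave well.

    The stack (z, y, x; z index 0 at the top) contains a bright shell
    along the well surface, a bright suspended sheet spanning the rim
    with planted center sag ``truth.sag`` (a paraboloid cap, so delta_h
    equals the sag), and cylindrical anchor bridges from
    ``truth.anchors``.  Voxels are pixel_size x pixel_size x voxel_z µm.
    """
    R = truth.well_radius
    s = truth.sag
    if s > R:
        raise ValueError("sag deeper than the well")
    ny, nx = truth.shape
    px, dz = truth.pixel_size, truth.voxel_z
    depth = R + 3 * shell
    nz = int(np.ceil(depth / dz)) + 1
    H_total = (nz - 1) * dz
    h_plane = H_total - shell

    x_um = (np.arange(nx) + 0.5) * px
    y_um = (np.arange(ny) + 0.5) * px
    X, Y = np.meshgrid(x_um, y_um)
    h_sub = well_substrate_height(truth, X, Y, h_plane)

    cx = nx * px / 2.0
    cy = ny * px / 2.0
    rho2 = (X - cx) ** 2 + (Y - cy) ** 2
    inside = rho2 < R * R
    h_sheet = np.where(inside, h_plane - s * (1.0 - rho2 / (R * R)), np.nan)

    z_height = (nz - 1 - np.arange(nz)) * dz     # µm above bottom per slice
    stack = np.full((nz, ny, nx), background)
    for k, h in enumerate(z_height):
        sub_hit = np.abs(h - h_sub) <= shell / 2.0
        sheet_hit = inside & (np.abs(h - h_sheet) <= shell / 2.0)
        sl = stack[k]
        sl[sub_hit] = 1.0
        sl[sheet_hit] = 1.0
        for (ax_um, ay_um, ar_um) in truth.anchors:
            d2 = (X - ax_um) ** 2 + (Y - ay_um) ** 2
            col = d2 <= ar_um**2
            between = col & (h > h_sub + shell / 2.0) & inside \
                & (h < np.where(np.isfinite(h_sheet), h_sheet, -np.inf)
                   - shell / 2.0)
            sl[between] = 1.0
    rng = truth.rng(_STREAM_SHEET)
    return _add_noise(stack, rng, truth.noise_sigma, truth.poisson_gain)


def synth_mesh(shape: str, resolution: int = 4, scale: float = 1.0):
    """Triangle mesh of a reference shape with closed-form K attached.

    Shapes: sphere, hemisphere, plane, torus, catenoid, sagging_sheet.
    Returns (trimesh.Trimesh, K_analytic per vertex or None).  The torus
    has tube radius scale/3 around a circle of radius ``scale``; the
    sagging sheet is a paraboloid cap over a disk (no closed-form K
    attached).
    """
    if resolution < 3:
        raise ValueError("resolution must be >= 3")
    R = float(scale)
    if shape == "sphere":
        m = trimesh.creation.icosphere(subdivisions=resolution, radius=R)
        K = np.full(len(m.vertices), 1.0 / R**2)
        return m, K
    if shape == "hemisphere":
        m = trimesh.creation.icosphere(subdivisions=resolution, radius=R)
        keep = np.flatnonzero((m.vertices[:, 2] > -1e-9)[m.faces].all(axis=1))
        m = m.submesh([keep], append=True)
        K = np.full(len(m.vertices), 1.0 / R**2)
        return m, K
    if shape == "plane":
        n = 2 ** resolution
        x = np.linspace(-R, R, n)
        xx, yy = np.meshgrid(x, x)
        m = _heightfield_mesh(xx, yy, np.zeros_like(xx))
        return m, np.zeros(len(m.vertices))
    if shape == "torus":
        r_tube = R / 3.0
        n_major = max(3 * 2 ** resolution, 48)
        n_minor = max(2 ** resolution * 2, 24)
        m = trimesh.creation.torus(major_radius=R, minor_radius=r_tube,
                                   major_sections=n_major,
                                   minor_sections=n_minor)
        v = np.asarray(m.vertices)
        rho = np.hypot(v[:, 0], v[:, 1])
        cosv = np.clip((rho - R) / r_tube, -1, 1)
        K = cosv / (r_tube * (R + r_tube * cosv))
        return m, K
    if shape == "catenoid":
        c = R
        t = np.linspace(-1.2 * c, 1.2 * c, 2 ** resolution)
        phi = np.linspace(0, 2 * np.pi, 2 ** resolution, endpoint=False)
        tt, pp = np.meshgrid(t, phi, indexing="ij")
        rr = c * np.cosh(tt / c)
        xx, yy, zz = rr * np.cos(pp), rr * np.sin(pp), tt
        m = _grid_mesh(xx, yy, zz, wrap_cols=True)
        tv = m.vertices[:, 2]
        K = -1.0 / (c**2 * np.cosh(tv / c) ** 4)
        return m, K
    if shape == "sagging_sheet":
        n = 2 ** resolution
        x = np.linspace(-1.5 * R, 1.5 * R, n)
        xx, yy = np.meshgrid(x, x)
        rho2 = xx**2 + yy**2
        sag = 0.2 * R
        zz = np.where(rho2 < R * R, -sag * (1 - rho2 / R**2), 0.0)
        m = _heightfield_mesh(xx, yy, zz)
        return m, None
    if shape == "concave_well":
        # spherical-cap imprint (rim radius R, sphere radius 1.25 R) in a
        # plane: the geometry a suspended sheet smooths out
        n = 2 ** resolution
        Rs = 1.25 * R
        x = np.linspace(-1.5 * R, 1.5 * R, n)
        xx, yy = np.meshgrid(x, x)
        rho2 = xx**2 + yy**2
        depth = np.sqrt(np.clip(Rs**2 - rho2, 0, None)) - np.sqrt(Rs**2 - R**2)
        zz = np.where(rho2 < R * R, -depth, 0.0)
        m = _heightfield_mesh(xx, yy, zz)
        return m, None
    raise ValueError(f"unknown shape {shape!r}")


def _heightfield_mesh(xx, yy, zz) -> trimesh.Trimesh:
    return _grid_mesh(xx, yy, zz, wrap_cols=False)


def _grid_mesh(xx, yy, zz, wrap_cols: bool = False) -> trimesh.Trimesh:
    ny, nx = xx.shape
    V = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    faces = []
    ncols = nx if wrap_cols else nx - 1
    for i in range(ny - 1):
        for j in range(ncols):
            j1 = (j + 1) % nx
            a = i * nx + j
            b = i * nx + j1
            c = (i + 1) * nx + j
            d = (i + 1) * nx + j1
            faces.append([a, b, d])
            faces.append([a, d, c])
    return trimesh.Trimesh(vertices=V, faces=np.asarray(faces), process=False)
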