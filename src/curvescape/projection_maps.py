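"""Top-view curvature rasters and distance-to-concavity maps.

A substrate patch is rasterized orthographically into co-registered
curvature maps at confocal resolution (0.60 µm pixels by default), so
fluorescence projections can be compared with the substrate geometry
pixel by pixel.  Curvatures are stored non-dimensionalized by the
design's sphere radius.  From the sign of the minimum principal
curvature kappa2 the module derives the distance map delta_{kappa2<0}:
for every pixel, the average of the Euclidean distances to the nearest
pixel with kappa2 <= 0 and to the nearest pixel with kappa2 < 0, which
weights kappa2 > 0 regions more heavily than kappa2 = 0 ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .surface_geometry import ParamPatch, SubstrateSpec

__all__ = [
    "CurvatureMapStack",
    "DistanceMap",
    "project_topview",
    "add_transition_band",
    "kappa2_sign_map",
    "distance_map",
]

#: normalized-curvature tolerance for sign ties (well below any designed
#: nonzero curvature, the smallest of which is order 0.1)
SIGN_EPS = 1e-3


@dataclass
class CurvatureMapStack:
    """Co-registered top-view rasters of substrate curvature.

    All rasters share shape (ny, nx); pixel centers sit at
    ((i + 0.5) * pixel_size, (j + 0.5) * pixel_size) from ``origin``.
    ``kappa1``/``kappa2``/``H``/``K`` are dimensionless (normalized by
    ``norm_radius``); ``pd_angle`` is the top-view angle of the kappa2
    principal direction in degrees in [0, 180) from the image horizontal,
    NaN where undefined (umbilics, vertical directions, background).
    """

    pixel_size: float
    norm_radius: float
    kappa1: np.ndarray
    kappa2: np.ndarray
    pd_angle: np.ndarray
    footprint: np.ndarray
    undefined_dir: np.ndarray
    origin: tuple = (0.0, 0.0)

    @property
    def H(self) -> np.ndarray:
        return 0.5 * (self.kappa1 + self.kappa2)

    @property
    def K(self) -> np.ndarray:
        return self.kappa1 * self.kappa2

    @property
    def shape(self):
        return self.kappa1.shape

    def copy(self) -> "CurvatureMapStack":
        return CurvatureMapStack(
            self.pixel_size, self.norm_radius,
            self.kappa1.copy(), self.kappa2.copy(), self.pd_angle.copy(),
            self.footprint.copy(), self.undefined_dir.copy(), self.origin)

    def save(self, directory) -> None:
        """Write float32 rasters plus a JSON sidecar with the metadata."""
        import tifffile

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name in ("kappa1", "kappa2", "pd_angle"):
            tifffile.imwrite(d / f"{name}.tif",
                             getattr(self, name).astype(np.float32))
        tifffile.imwrite(d / "footprint.tif",
                         self.footprint.astype(np.uint8))
        tifffile.imwrite(d / "undefined_dir.tif",
                         self.undefined_dir.astype(np.uint8))
        (d / "maps.json").write_text(json.dumps({
            "pixel_size_um": self.pixel_size,
            "norm_radius_um": self.norm_radius,
            "origin_um": list(self.origin),
        }, indent=2))

    @classmethod
    def load(cls, directory) -> "CurvatureMapStack":
        import tifffile

        d = Path(directory)
        meta = json.loads((d / "maps.json").read_text())
        return cls(
            meta["pixel_size_um"], meta["norm_radius_um"],
            tifffile.imread(d / "kappa1.tif").astype(float),
            tifffile.imread(d / "kappa2.tif").astype(float),
            tifffile.imread(d / "pd_angle.tif").astype(float),
            tifffile.imread(d / "footprint.tif").astype(bool),
            tifffile.imread(d / "undefined_dir.tif").astype(bool),
            tuple(meta.get("origin_um", (0.0, 0.0))))


@dataclass
class DistanceMap:
    """delta_{kappa2<0} raster (µm) and its two component transforms."""

    delta: np.ndarray
    d_le: np.ndarray   # distance to kappa2 <= 0
    d_lt: np.ndarray   # distance to kappa2 < 0
    pixel_size: float


def project_topview(patch: ParamPatch, pixel_size: float = 0.60,
                    norm_radius: float = 180.0, margin: float = 30.0,
                    shape: tuple | None = None) -> CurvatureMapStack:
    """Orthographic top-view rasterization of a patch.

    Each footprint pixel carries the curvatures of the topmost surface
    sample falling on it (a z-buffer over the patch samples); pixels
    outside the footprint are planar (kappa = 0).  The patch must be
    sampled densely enough that neighboring samples land on adjacent
    pixels; a sparse patch leaves pinholes in the footprint, which are
    closed by a one-pixel morphological closing.

    ``pd_angle`` is the in-plane direction of pd2 (the kappa2 direction),
    in degrees from the image x axis, undefined at umbilics and where pd2
    is vertical (silhouette parallels).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    xyz = patch.xyz.reshape(-1, 3)
    k1 = patch.kappa1.ravel() * norm_radius
    k2 = patch.kappa2.ravel() * norm_radius
    pd2 = patch.pd2.reshape(-1, 3)
    umb = patch.umbilic.ravel()
    keep = ~patch.flagged.ravel()
    xyz, k1, k2, pd2, umb = xyz[keep], k1[keep], k2[keep], pd2[keep], umb[keep]

    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    if shape is None:
        x0 = x.min() - margin
        y0 = y.min() - margin
        nx = int(np.ceil((x.max() + margin - x0) / pixel_size))
        ny = int(np.ceil((y.max() + margin - y0) / pixel_size))
    else:
        ny, nx = shape
        x0 = y0 = 0.0
    ix = np.floor((x - x0) / pixel_size).astype(int)
    iy = np.floor((y - y0) / pixel_size).astype(int)
    ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    ix, iy, z = ix[ok], iy[ok], z[ok]
    k1, k2, pd2, umb = k1[ok], k2[ok], pd2[ok], umb[ok]

    flat = iy * nx + ix
    # per pixel keep the sample of largest |z|: the topmost point for a
    # protrusion, and the mirror-symmetric choice for an imprint, so convex
    # and concave variants of one design rasterize identically
    order = np.lexsort((np.abs(z), flat))
    flat_s = flat[order]
    last = np.r_[flat_s[1:] != flat_s[:-1], True]
    sel = order[last]
    pix = flat_s[last]

    K1 = np.zeros(ny * nx)
    K2 = np.zeros(ny * nx)
    PD = np.full(ny * nx, np.nan)
    FOOT = np.zeros(ny * nx, bool)
    UND = np.zeros(ny * nx, bool)

    K1[pix] = k1[sel]
    K2[pix] = k2[sel]
    FOOT[pix] = True
    # in-plane projection of pd2
    vx, vy = pd2[sel, 0], pd2[sel, 1]
    plen = np.hypot(vx, vy)
    und = umb[sel] | ~np.isfinite(plen) | (plen < 1e-6)
    ang = np.degrees(np.arctan2(vy, vx)) % 180.0
    PD[pix] = np.where(und, np.nan, ang)
    UND[pix] = und

    K1 = K1.reshape(ny, nx)
    K2 = K2.reshape(ny, nx)
    PD = PD.reshape(ny, nx)
    FOOT = FOOT.reshape(ny, nx)
    UND = UND.reshape(ny, nx)

    # close pinholes left by sampling: fill with the local footprint median
    holes = ndimage.binary_closing(FOOT, structure=np.ones((3, 3))) & ~FOOT
    if holes.any():
        for arr in (K1, K2):
            filled = ndimage.grey_dilation(arr, size=3)
            arr[holes] = filled[holes]
        FOOT |= holes
        UND[holes] = True
    UND[~FOOT] = True
    PD[~FOOT] = np.nan

    # keep per-pixel ordering invariant
    k1f, k2f = np.maximum(K1, K2), np.minimum(K1, K2)
    return CurvatureMapStack(pixel_size, norm_radius, k1f, k2f, PD,
                             FOOT, UND, (x0, y0))


def add_transition_band(stack: CurvatureMapStack, radius: float = 15.0,
                        convexity: str = "convex") -> CurvatureMapStack:
    """Assign the curved-to-planar transition fillet its design curvature.

    A band of width ``radius`` (µm) of flat pixels adjacent to the
    footprint receives a principal curvature of magnitude 1/radius: the
    fillet at the foot of a convex substrate is locally concave
    (kappa2 = -1/radius), the rim of a concave well locally convex
    (kappa1 = +1/radius).  Curvatures are re-sorted and H, K follow from
    the principal values.  ``radius = 0`` returns the stack unchanged.
    """
    if radius < 0:
        raise ValueError("band radius must be >= 0")
    if radius == 0:
        return stack
    out = stack.copy()
    if not stack.footprint.any():
        raise ValueError("empty footprint")
    n_band_px = radius / stack.pixel_size
    ny, nx = stack.shape
    if 2 * n_band_px > max(ny, nx):
        raise ValueError("transition band wider than the raster")
    dist = ndimage.distance_transform_edt(
        ~stack.footprint, sampling=stack.pixel_size)
    band = (dist > 0) & (dist <= radius)
    k_band = stack.norm_radius / radius
    if convexity == "convex":
        out.kappa1[band] = 0.0
        out.kappa2[band] = -k_band
    elif convexity == "concave":
        out.kappa1[band] = k_band
        out.kappa2[band] = 0.0
    else:
        raise ValueError(f"convexity must be convex/concave, got {convexity!r}")
    lo = np.minimum(out.kappa1[band], out.kappa2[band])
    hi = np.maximum(out.kappa1[band], out.kappa2[band])
    out.kappa1[band], out.kappa2[band] = hi, lo
    # fillet runs parallel to the boundary; its kappa-band direction is the
    # boundary tangent, which we leave undefined rather than estimate
    out.pd_angle[band] = np.nan
    out.undefined_dir[band] = True
    out.footprint[band] = True
    return out


def kappa2_sign_map(stack: CurvatureMapStack, eps: float = SIGN_EPS) -> np.ndarray:
    """Ternary raster of sign(kappa2) with tolerance ``eps``."""
    s = np.zeros(stack.shape, dtype=np.int8)
    s[stack.kappa2 > eps] = 1
    s[stack.kappa2 < -eps] = -1
    return s


def distance_map(stack: CurvatureMapStack, eps: float = SIGN_EPS) -> DistanceMap:
    """Euclidean distance (µm) to the nearest concave-direction region.

    delta = (d_{kappa2<=0} + d_{kappa2<0}) / 2, the average of the
    distance transforms to pixels with kappa2 <= 0 and kappa2 < 0, so
    convex regions (kappa2 > 0) score higher than developable ones
    (kappa2 = 0).  Distances use pixel-center metric scaled to µm.
    """
    sign = kappa2_sign_map(stack, eps)
    neg = sign < 0
    nonpos = sign <= 0
    if not neg.any():
        raise ValueError("no pixels with kappa2 < 0; distance map undefined")
    d_lt = ndimage.distance_transform_edt(~neg, sampling=stack.pixel_size)
    d_le = ndimage.distance_transform_edt(~nonpos, sampling=stack.pixel_size)
    return DistanceMap(0.5 * (d_le + d_lt), d_le, d_lt, stack.pixel_size)
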