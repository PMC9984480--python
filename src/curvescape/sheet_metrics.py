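"""Suspended-cell-sheet displacement and anchor density from z-stacks.

Cells spanning concave wells detach into suspended sheets anchored to
the substrate by actin bridges.  From an actin z-stack the module
reslices cross-sections (5 µm spacing by default), traces the sheet as
the topmost bright path of the middle section, measures the maximum
vertical displacement delta_h of the sheet relative to the chord through
its endpoints, and measures the anchor density as the fraction of
actin-positive voxels in the region between the sheet and the substrate
surface.  Across specimens, delta_h and anchor density are correlated
with Spearman's rank coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import ndimage, stats
from skimage import filters

__all__ = [
    "SheetProfile",
    "AnchorStats",
    "reslice_stack",
    "trace_sheet",
    "anchor_density",
    "correlate_dh_anchors",
]


@dataclass
class SheetProfile:
    """Traced sheet polyline of one cross-section.

    ``x`` lateral positions (µm), ``height`` sheet heights (µm, NaN at
    untraceable columns); ``delta_h`` is the maximum vertical deviation
    from the chord through the endpoints, or NaN when the sheet does not
    span (``spanning`` False).
    """

    x: np.ndarray
    height: np.ndarray
    delta_h: float
    spanning: bool

    @property
    def endpoints(self):
        i = np.flatnonzero(np.isfinite(self.height))
        if i.size == 0:
            return None
        return ((self.x[i[0]], self.height[i[0]]),
                (self.x[i[-1]], self.height[i[-1]]))


@dataclass
class AnchorStats:
    """Fraction of actin-positive voxels below the detached sheet."""

    anchor_density: float
    positive_voxels: int
    region_voxels: int


def reslice_stack(zstack: np.ndarray, voxel_size: tuple,
                  spacing: float = 5.0) -> tuple[np.ndarray, tuple]:
    """Orthogonal (x-z) cross-sections of a (z, y, x) stack.

    Sections are sampled every ``spacing`` µm along y with linear
    interpolation; ``voxel_size`` is (dz, dy, dx) in µm.  Returns
    (sections, section_voxel) where sections has shape (n_sections, nz,
    nx) and section_voxel is the (dz, dx) spacing of each section.
    A spacing finer than dy triggers an upsampling warning.
    """
    zstack = np.asarray(zstack, float)
    if zstack.ndim != 3:
        raise ValueError("expected a (z, y, x) stack")
    dz, dy, dx = (float(v) for v in voxel_size)
    if min(dz, dy, dx) <= 0 or spacing <= 0:
        raise ValueError("voxel sizes and spacing must be positive")
    if spacing < dy:
        warnings.warn("reslice spacing finer than the y voxel size "
                      "(upsampling)", stacklevel=2)
    ny = zstack.shape[1]
    y_um = np.arange(0.0, (ny - 1) * dy + 1e-9, spacing)
    y_idx = y_um / dy
    nz, nx = zstack.shape[0], zstack.shape[2]
    zz, yy, xx = np.meshgrid(np.arange(nz), y_idx, np.arange(nx),
                             indexing="ij")
    out = ndimage.map_coordinates(zstack, [zz, yy, xx], order=1)
    sections = np.moveaxis(out, 1, 0)      # (n_sections, nz, nx)
    return sections, (dz, dx)


def trace_sheet(section: np.ndarray, voxel: tuple, threshold="otsu",
                max_gap: int = 2) -> SheetProfile:
    """Trace the suspended sheet in one cross-section.

    The sheet is the topmost supra-threshold voxel per column (z index 0
    = top of the stack; heights are reported as µm above the bottom of
    the section).  Columns with no signal inside the lateral span are
    gaps; if more than ``max_gap`` consecutive columns are empty the
    sheet is flagged non-spanning and delta_h is NaN.  delta_h is the
    maximum vertical deviation of the traced polyline from the chord
    through its endpoints.
    """
    section = np.asarray(section, float)
    dzv, dxv = float(voxel[0]), float(voxel[1])
    if threshold == "otsu":
        if section.max() == section.min():
            return SheetProfile(np.arange(section.shape[1]) * dxv,
                                np.full(section.shape[1], np.nan), np.nan, False)
        thr = filters.threshold_otsu(section)
    else:
        thr = float(threshold)
    nz, nx = section.shape
    mask = section > thr
    top = np.argmax(mask, axis=0)                 # first bright voxel from top
    has = mask.any(axis=0)
    height = np.where(has, (nz - 1 - top) * dzv, np.nan)
    x = np.arange(nx) * dxv

    cols = np.flatnonzero(has)
    if cols.size < 2:
        return SheetProfile(x, height, np.nan, False)
    i0, i1 = cols[0], cols[-1]
    inner = has[i0:i1 + 1]
    spanning = True
    if not inner.all():
        # longest run of consecutive empty columns inside the span
        runs = np.diff(np.flatnonzero(np.r_[True, inner, True]))
        if (runs - 1).max() > max_gap:
            spanning = False
    if not spanning:
        return SheetProfile(x, height, np.nan, False)
    # chord through the endpoints
    h0, h1 = height[i0], height[i1]
    chord = h0 + (h1 - h0) * (x - x[i0]) / max(x[i1] - x[i0], 1e-12)
    dev = np.abs(height - chord)
    delta_h = float(np.nanmax(dev[i0:i1 + 1]))
    return SheetProfile(x, height, delta_h, True)


def anchor_density(sections: np.ndarray, voxel: tuple, profiles,
                   substrate_height, threshold="otsu",
                   margin: float | None = None) -> AnchorStats:
    """Density of actin voxels between the sheet and the substrate.

    ``sections`` is the resliced (n, nz, nx) stack, ``profiles`` the
    traced SheetProfile per section, and ``substrate_height`` an (n, nx)
    array of substrate surface heights (µm above section bottom), taken
    from the substrate design rather than from imaging.  The stack is
    binarized (Otsu over the whole stack by default) and the density is
    positive voxels / region voxels over all voxels strictly between
    sheet and substrate.  ``margin`` (µm, default twice the section z
    voxel) excludes voxels adjacent to the sheet and the substrate shell,
    whose brightness belongs to those structures, not to anchors.
    """
    sections = np.asarray(sections, float)
    dzv, _ = float(voxel[0]), float(voxel[1])
    n, nz, nx = sections.shape
    substrate_height = np.asarray(substrate_height, float)
    if substrate_height.shape != (n, nx):
        raise ValueError("substrate_height must be (n_sections, nx)")
    if threshold == "otsu":
        thr = filters.threshold_otsu(sections)
    else:
        thr = float(threshold)
    binary = sections > thr
    if margin is None:
        margin = 2.0 * dzv
    z_height = (nz - 1 - np.arange(nz)) * dzv     # µm above bottom, per z index
    region = np.zeros_like(binary)
    for k, prof in enumerate(profiles):
        sheet = prof.height                        # (nx,)
        below = (z_height[:, None] < sheet[None, :] - margin)
        above = (z_height[:, None] > substrate_height[k][None, :] + margin)
        ok = np.isfinite(sheet)[None, :]
        region[k] = below & above & ok
    nreg = int(region.sum())
    if nreg == 0:
        return AnchorStats(np.nan, 0, 0)
    npos = int((binary & region).sum())
    return AnchorStats(npos / nreg, npos, nreg)


def correlate_dh_anchors(delta_h, density):
    """Spearman rank correlation between delta_h and anchor density.

    Two-tailed p-value; exact (permutation over all orderings) for
    n <= 9, asymptotic otherwise.  Requires at least 5 paired samples;
    returns (r, p), with r NaN when either variable is all ties.
    """
    dh = np.asarray(delta_h, float)
    de = np.asarray(density, float)
    if dh.shape != de.shape or dh.ndim != 1:
        raise ValueError("paired 1-d samples required")
    n = dh.size
    if n < 5:
        raise ValueError("need at least 5 paired samples")
    if np.unique(dh).size == 1 or np.unique(de).size == 1:
        return np.nan, np.nan
    r, p_asym = stats.spearmanr(dh, de)
    if n <= 9:
        rx = stats.rankdata(dh)
        ry = stats.rankdata(de)
        obs = np.corrcoef(rx, ry)[0, 1]
        count = 0
        total = 0
        for perm in permutations(ry):
            rp = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(rp) >= abs(obs) - 1e-12:
                count += 1
            total += 1
        return float(r), count / total
    return float(r), float(p_asym)
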