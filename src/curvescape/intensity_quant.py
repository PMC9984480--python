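"""Actin-intensity quantification against curvature and distance maps.

Projected fluorescence images are normalized to unit mean, downsampled
into superpixels (block means), and compared with the co-registered
curvature rasters: intensity grouped by sign(kappa2), binned over the
(kappa1, kappa2) plane, and correlated (Spearman) with the distance map
delta_{kappa2<0}.  Frequency maps sum normalized images over their
periodic units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IntensityRaster",
    "FrequencyMap",
    "register_roi",
    "normalize_intensity",
    "rasterize_superpixels",
    "build_frequency_map",
    "intensity_vs_kappa2_sign",
    "intensity_heatmap",
    "intensity_vs_distance",
    "roi_mean_intensity_compare",
    "max_intensity_projection",
]


@dataclass
class IntensityRaster:
    """Superpixel grid of mean normalized intensity.

    Each value is the arithmetic mean of the ``superpixel_size`` x
    ``superpixel_size`` pixel block it covers; trailing partial blocks of
    the source image are dropped.
    """

    values: np.ndarray
    superpixel_size: int

    @property
    def shape(self):
        return self.values.shape


@dataclass
class FrequencyMap:
    """Summed normalized-intensity raster over stacked periodic units."""

    values: np.ndarray
    n_images: int
    n_units: int


def max_intensity_projection(zstack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (z, y, x) stack."""
    zstack = np.asarray(zstack)
    if zstack.ndim != 3:
        raise ValueError("expected a (z, y, x) stack")
    return zstack.max(axis=0)


def register_roi(image: np.ndarray, corner: tuple, size: tuple,
                 rotate_to_vertical: bool = True) -> np.ndarray:
    """Crop a rectangular ROI and rotate its long axis vertical.

    ``corner`` is the (row, col) of the ROI's top-left pixel and ``size``
    its (height, width).  If the cropped ROI is wider than tall and
    ``rotate_to_vertical`` is set, it is rotated by 90 degrees so the long
    axis runs vertically (the orientation in which periodic substrates
    repeat down the image).
    """
    image = np.asarray(image)
    r0, c0 = int(corner[0]), int(corner[1])
    h, w = int(size[0]), int(size[1])
    if h <= 0 or w <= 0:
        raise ValueError("ROI size must be positive")
    if r0 < 0 or c0 < 0 or r0 + h > image.shape[0] or c0 + w > image.shape[1]:
        raise ValueError("ROI outside image")
    roi = image[r0:r0 + h, c0:c0 + w]
    if rotate_to_vertical and w > h:
        roi = np.rot90(roi, k=-1)
    return roi.copy()


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Normalize an image to unit mean intensity."""
    image = np.asarray(image, float)
    m = image.mean()
    if not np.isfinite(m) or m <= 0:
        raise ValueError("cannot normalize an empty or all-zero image")
    return image / m


def rasterize_superpixels(image: np.ndarray, size: int) -> IntensityRaster:
    """Downsample an image into superpixels of ``size`` x ``size`` pixels.

    Each superpixel is the mean of its member pixels.  Trailing rows and
    columns that do not fill a complete block are dropped, so block means
    are never biased by partial blocks.
    """
    image = np.asarray(image, float)
    size = int(size)
    if size < 1:
        raise ValueError("superpixel size must be >= 1")
    ny, nx = image.shape[0] // size, image.shape[1] // size
    if ny == 0 or nx == 0:
        raise ValueError("superpixel size larger than image")
    block = image[:ny * size, :nx * size].reshape(ny, size, nx, size)
    return IntensityRaster(block.mean(axis=(1, 3)), size)


def build_frequency_map(images, unit_rows: int) -> FrequencyMap:
    """Sum normalized images over their periodic units.

    Every image is normalized to unit mean, all images are summed, the sum
    is split along the vertical (periodic) axis into units of
    ``unit_rows`` rows, and the units are summed into the final map.  The
    image height must be a whole number of units; otherwise the error
    message suggests the largest commensurate crop.
    """
    images = [np.asarray(im, float) for im in images]
    if not images:
        raise ValueError("need at least one image")
    shape = images[0].shape
    if any(im.shape != shape for im in images):
        raise ValueError("images must share a common shape")
    unit_rows = int(unit_rows)
    if unit_rows < 1:
        raise ValueError("unit_rows must be >= 1")
    if shape[0] % unit_rows != 0:
        crop = (shape[0] // unit_rows) * unit_rows
        raise ValueError(
            f"image height {shape[0]} is not a whole number of {unit_rows}-row "
            f"units; crop to {crop} rows first")
    total = np.zeros(shape)
    for im in images:
        total += normalize_intensity(im)
    n_units = shape[0] // unit_rows
    units = total.reshape(n_units, unit_rows, shape[1])
    return FrequencyMap(units.sum(axis=0), len(images), n_units)


def intensity_vs_kappa2_sign(raster: IntensityRaster, sign_map: np.ndarray,
                             n_samples: int = 100, seed: int = 0) -> pd.DataFrame:
    """Sample superpixel intensities per sign(kappa2) category.

    ``sign_map`` must be registered to the raster grid (one ternary value
    per superpixel; a pixel-level map is reduced by majority).  For each
    category present, ``n_samples`` superpixels are drawn uniformly
    without replacement (all of them, with a warning, if fewer exist).
    Returns a tidy frame with columns ``sign`` and ``intensity`` ready for
    a Mann-Whitney or ANOVA-style comparison.
    """
    values = raster.values
    sign_map = np.asarray(sign_map)
    if sign_map.shape != values.shape:
        sign_map = _majority_downsample(sign_map, values.shape)
    rng = np.random.default_rng(seed)
    rows = []
    for s in (-1, 0, 1):
        pool = values[sign_map == s]
        if pool.size == 0:
            continue
        k = min(int(n_samples), pool.size)
        if k < n_samples:
            warnings.warn(
                f"sign {s}: only {pool.size} superpixels available "
                f"(< {n_samples}); sampling all", stacklevel=2)
        take = rng.choice(pool.size, size=k, replace=False) if k else []
        for v in pool[take]:
            rows.append((s, v))
    return pd.DataFrame(rows, columns=["sign", "intensity"])


def mannwhitney_by_sign(table: pd.DataFrame, a: int = -1, b: int = 1):
    """Two-sided Mann-Whitney U between two sign groups of a sample table."""
    ga = table.loc[table["sign"] == a, "intensity"].to_numpy()
    gb = table.loc[table["sign"] == b, "intensity"].to_numpy()
    if ga.size == 0 or gb.size == 0:
        raise ValueError("both groups must be nonempty")
    return stats.mannwhitneyu(ga, gb, alternative="two-sided")


def _majority_downsample(pixel_map: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a pixel-level label map to a superpixel grid by majority."""
    ny, nx = shape
    sy = pixel_map.shape[0] // ny
    sx = pixel_map.shape[1] // nx
    if sy < 1 or sx < 1:
        raise ValueError("sign map smaller than raster grid")
    block = pixel_map[:ny * sy, :nx * sx].reshape(ny, sy, nx, sx)
    out = np.zeros((ny, nx), dtype=np.int8)
    counts = np.stack([(block == s).sum(axis=(1, 3)) for s in (-1, 0, 1)])
    out = np.array([-1, 0, 1], dtype=np.int8)[counts.argmax(axis=0)]
    return out


def intensity_heatmap(raster20: IntensityRaster, kappa1_map: np.ndarray,
                      kappa2_map: np.ndarray, bins: int = 40,
                      extent: tuple | None = None):
    """Median superpixel intensity binned over the (kappa1, kappa2) plane.

    ``kappa1_map``/``kappa2_map`` are per-superpixel normalized curvatures
    registered to the raster (pixel-level maps are block-averaged).
    Returns (heatmap, kappa1_edges, kappa2_edges); empty cells are NaN.
    Only the half-plane kappa1 >= kappa2 can be populated.
    """
    vals = raster20.values.ravel()
    k1 = _match_grid(kappa1_map, raster20).ravel()
    k2 = _match_grid(kappa2_map, raster20).ravel()
    if extent is None:
        lo = min(k1.min(), k2.min())
        hi = max(k1.max(), k2.max())
        pad = 1e-9 + 0.001 * (hi - lo)
        extent = (lo - pad, hi + pad)
    stat, e1, e2, _ = stats.binned_statistic_2d(
        k1, k2, vals, statistic="median", bins=bins, range=[extent, extent])
    return stat, e1, e2


def _match_grid(pixel_map: np.ndarray, raster: IntensityRaster) -> np.ndarray:
    pixel_map = np.asarray(pixel_map, float)
    if pixel_map.shape == raster.shape:
        return pixel_map
    return rasterize_superpixels(pixel_map, raster.superpixel_size).values


def intensity_vs_distance(raster: IntensityRaster, dmap, bin_width: float = 2.0):
    """Superpixel intensity versus distance-to-concavity delta.

    Pairs each superpixel's intensity with the block-mean of the delta
    map; returns (pairs frame, binned frame, spearman result).  The
    binned frame holds per-delta-bin median and quartiles; Spearman's r
    (two-tailed) is computed on the unbinned pairs and reported as NaN
    when intensity is constant.
    """
    delta = rasterize_superpixels(dmap.delta, raster.superpixel_size).values
    if delta.shape != raster.shape:
        raise ValueError("raster and distance map are not registered")
    pairs = pd.DataFrame({
        "delta": delta.ravel(), "intensity": raster.values.ravel()})
    if pairs["intensity"].nunique() <= 1:
        rho, p = np.nan, np.nan
    else:
        rho, p = stats.spearmanr(pairs["delta"], pairs["intensity"])
    edges = np.arange(0.0, pairs["delta"].max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    which = np.digitize(pairs["delta"], edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        v = pairs["intensity"].to_numpy()[which == b]
        if v.size == 0:
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append((0.5 * (edges[b] + edges[b + 1]), med, q1, q3, v.size))
    binned = pd.DataFrame(rows, columns=["delta", "median", "q1", "q3", "n"])
    return pairs, binned, (rho, p)


def roi_mean_intensity_compare(image: np.ndarray, rois, labels) -> pd.DataFrame:
    """Normalized mean intensity of square ROIs, labeled by sign(kappa2).

    ``rois`` is a sequence of (row, col, side) squares; each ROI's mean
    intensity is divided by the mean of all ROI means in the image, so the
    within-image average is 1.  Overlapping ROIs are allowed but warned
    about.  Returns a frame with columns ``label`` and ``intensity``.
    """
    image = np.asarray(image, float)
    if len(rois) < 2:
        raise ValueError("need at least two ROIs per image")
    if len(labels) != len(rois):
        raise ValueError("one label per ROI required")
    cover = np.zeros(image.shape, dtype=np.int16)
    means = []
    for (r, c, side) in rois:
        r, c, side = int(r), int(c), int(side)
        if r < 0 or c < 0 or r + side > image.shape[0] or c + side > image.shape[1]:
            raise ValueError("ROI outside image")
        cover[r:r + side, c:c + side] += 1
        means.append(image[r:r + side, c:c + side].mean())
    if (cover > 1).any():
        warnings.warn("ROIs overlap", stacklevel=2)
    means = np.asarray(means)
    grand = means.mean()
    if grand <= 0:
        raise ValueError("all ROIs are empty")
    return pd.DataFrame({"label": list(labels), "intensity": means / grand})
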