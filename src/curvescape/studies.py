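"""End-to-end recovery studies on synthetic scenes.

Each function generates ground-truthed synthetic data with the scene
generators, runs the corresponding quantification pipeline, and returns
the planted and recovered quantities.  They are the single code path
behind the analysis drivers, the acceptance tests and the acceptance
script, so every reported number is recomputed from scratch.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit
from scipy import stats

from .intensity_quant import (
    intensity_vs_distance, normalize_intensity, rasterize_superpixels)
from .nuclei_quant import density_vs_distance
from .projection_maps import add_transition_band, distance_map, project_topview
from .sf_orientation import acute_angle_difference, fft_dominant_orientation
from .sheet_metrics import (
    anchor_density, correlate_dh_anchors, reslice_stack, trace_sheet)
from .surface_geometry import SubstrateSpec, make_patch, normalize_curvature
from .synthetic_data import (
    SceneTruth, striped_tile, synth_actin_image, synth_nuclei_image,
    synth_sheet_stack, well_substrate_height)

__all__ = [
    "sphere_normalized_curvature",
    "cylinder_normalized_curvature",
    "sphere_distance_scene",
    "orientation_rms_on_stripes",
    "recover_lambda_I",
    "recover_lambda_n",
    "spearman_sign_rate",
    "spearman_type_one_error",
    "recover_sheet_sag",
    "recover_anchor_density",
    "dh_anchor_cohort",
]


def sphere_normalized_curvature(n_samples: int = 256):
    """Normalized kappa1/kappa2 of the convex 180 µm spherical substrate.

    Returns (common value, n interior samples); the two principal
    curvatures agree to 1e-12 on the sphere, so their mean is reported.
    """
    spec = SubstrateSpec("spheres", n_periods=1)
    patch = make_patch(spec, n_samples, 65)
    ok = ~patch.flagged
    k1 = normalize_curvature(patch.kappa1[ok], spec)
    k2 = normalize_curvature(patch.kappa2[ok], spec)
    assert np.abs(k1 - k2).max() < 1e-9
    return float(np.mean(0.5 * (k1 + k2))), int(ok.sum())


def cylinder_normalized_curvature(n_samples: int = 256):
    """Max |K| and |kappa2| of the plain cylinder substrate (normalized).

    Returns (max of the two maxima, n grid samples).
    """
    spec = SubstrateSpec("cylinder")
    patch = make_patch(spec, n_samples, 65)
    K = normalize_curvature(normalize_curvature(patch.K, spec), spec)
    k2 = normalize_curvature(patch.kappa2, spec)
    val = max(float(np.abs(K).max()), float(np.abs(k2).max()))
    return val, int(patch.K.size)


def sphere_distance_scene(n_periods: int = 2, pixel_size: float = 0.6,
                          n_samples: int = 900):
    """Convex spheres substrate -> banded curvature maps -> distance map."""
    spec = SubstrateSpec("spheres", n_periods=n_periods)
    patch = make_patch(spec, n_samples, n_samples)
    stack = project_topview(patch, pixel_size, spec.sphere_radius, margin=30.0)
    stack = add_transition_band(stack, 15.0, "convex")
    return spec, stack, distance_map(stack)


def orientation_rms_on_stripes(seed: int, n_tiles: int = 100,
                               snr: float = 5.0, angle: float = 30.0,
                               size: int = 80, period: float = 8.0):
    """RMS angular error of the FFT estimator over seeded striped tiles."""
    errs = []
    for k in range(n_tiles):
        tile = striped_tile(size, angle, period=period, snr=snr,
                            seed=seed * 100_003 + k)
        est, _ = fft_dominant_orientation(tile)
        errs.append(acute_angle_difference(est, angle))
    errs = np.asarray(errs)
    return float(np.sqrt((errs**2).mean()))


def recover_lambda_I(seed: int, dmap=None, superpixel: int = 12):
    """Plant an exponential intensity decay versus delta and re-fit it.

    Builds the spheres-substrate distance map, synthesizes an actin image
    whose local mean is modulated by 1 + a*exp(-delta/lambda_I), runs the
    superpixel intensity-versus-distance pipeline and fits the decay.
    Returns (lambda_true, lambda_hat, n_superpixels, spearman_r).
    """
    if dmap is None:
        _, _, dmap = sphere_distance_scene()
    truth = SceneTruth(seed=seed, shape=dmap.delta.shape,
                       pixel_size=dmap.pixel_size)
    img = synth_actin_image(truth, delta=dmap.delta)
    raster = rasterize_superpixels(normalize_intensity(img), superpixel)
    pairs, _, (rho, _) = intensity_vs_distance(raster, dmap)
    popt, _ = curve_fit(
        lambda d, A, C, lam: A * (1 + C * np.exp(-d / lam)),
        pairs["delta"], pairs["intensity"], p0=(1.0, 1.0, 20.0),
        maxfev=20_000)
    return truth.lambda_I, float(popt[2]), len(pairs), float(rho)


def recover_lambda_n(seed: int, dmap=None, n_nuclei: int = 5000,
                     bin_width: float = 2.0):
    """Plant nuclei with density exp(-delta/lambda_n) and re-fit the decay.

    Nuclei are rejection-sampled from the planted density over the
    spheres-substrate distance map; the area-normalized density-vs-delta
    pipeline is fitted with an exponential.  Returns
    (lambda_true, lambda_hat, n_nuclei).
    """
    if dmap is None:
        _, _, dmap = sphere_distance_scene()
    truth = SceneTruth(seed=seed, shape=dmap.delta.shape,
                       pixel_size=dmap.pixel_size, n_nuclei=n_nuclei)
    _, gt = synth_nuclei_image(truth, delta=dmap.delta, render=False)
    frame, _ = density_vs_distance(gt, dmap, bin_width=bin_width)
    sel = (frame["n_pixels"] > 50) & (frame["delta"] < 4 * truth.lambda_n)
    popt, _ = curve_fit(
        lambda d, A, lam: A * np.exp(-d / lam),
        frame["delta"][sel], frame["density"][sel],
        p0=(frame["density"].max(), 20.0), maxfev=20_000)
    return truth.lambda_n, float(popt[1]), len(gt)


def spearman_sign_rate(seed: int, reps: int = 40, shape=(320, 320),
                       superpixel: int = 20):
    """Fraction of seeded scenes whose planted decay yields Spearman r < 0."""
    rng = np.random.default_rng(seed)
    delta = None
    hits = 0
    for k in range(reps):
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        delta = np.abs(xx - shape[1] / 2) * 0.6
        truth = SceneTruth(seed=seed * 7919 + k, shape=shape)
        img = synth_actin_image(truth, delta=delta)
        raster = rasterize_superpixels(normalize_intensity(img), superpixel)
        from .projection_maps import DistanceMap
        dm = DistanceMap(delta, delta, delta, 0.6)
        _, _, (rho, _) = intensity_vs_distance(raster, dm)
        if rho < 0:
            hits += 1
    return hits / reps


def spearman_type_one_error(seed: int, reps: int = 1000, n: int = 1000,
                            alpha: float = 0.05):
    """Rejection rate of the Spearman test under an independent null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if stats.spearmanr(x, y).pvalue < alpha:
            rejections += 1
    return rejections / reps


def _sheet_scene(seed: int, sag: float, anchors=(), shape=(300, 300),
                 well_radius: float = 80.0, noise_sigma: float = 0.05):
    truth = SceneTruth(seed=seed, shape=shape, well_radius=well_radius,
                       sag=sag, anchors=anchors, noise_sigma=noise_sigma)
    stack = synth_sheet_stack(truth)
    secs, vox = reslice_stack(stack, (truth.voxel_z, truth.pixel_size,
                                      truth.pixel_size), spacing=5.0)
    return truth, stack, secs, vox


def recover_sheet_sag(seed: int, sag: float = 40.0):
    """Planted sag versus traced delta_h; returns (sag, delta_h, spacing)."""
    truth, _, secs, vox = _sheet_scene(seed, sag)
    prof = trace_sheet(secs[secs.shape[0] // 2], vox)
    return sag, float(prof.delta_h), 5.0


def recover_anchor_density(seed: int, sag: float = 15.0):
    """Measured anchor density versus the planted voxel volume fraction.

    The planted fraction is counted on the noiseless voxelization of the
    same scene over the identical sub-sheet region, so the comparison
    isolates the binarize-and-count pipeline.
    Returns (planted_fraction, measured_density).
    """
    cx = 300 * 0.6 / 2
    anchors = ((cx - 30, cx, 9.0), (cx + 25, cx + 10, 9.0), (cx, cx - 35, 9.0))

    def measure(noise):
        truth, _, secs, vox = _sheet_scene(seed, sag, anchors,
                                           noise_sigma=noise)
        profiles = [trace_sheet(s, vox, threshold=0.5) for s in secs]
        nsec, nz, nx = secs.shape
        x_um = (np.arange(nx) + 0.5) * truth.pixel_size
        H_total = (nz - 1) * truth.voxel_z
        sub = np.stack([
            well_substrate_height(truth, x_um,
                                  np.full(nx, k * 5.0 + 0.3), H_total - 3.0)
            for k in range(nsec)])
        thr = 0.5 if noise == 0.0 else "otsu"
        return anchor_density(secs, vox, profiles, sub, threshold=thr)

    planted = measure(0.0)
    measured = measure(0.05)
    return planted.anchor_density, measured.anchor_density


def dh_anchor_cohort(seed: int, n_specimens: int = 10):
    """Simulated specimen cohort with a monotone sag-anchor link.

    Each specimen's planted anchor count grows with its sag; delta_h and
    anchor density are measured from the stacks and correlated.
    Returns (spearman_r, p).
    """
    rng = np.random.default_rng(seed)
    dh, dens = [], []
    for i in range(n_specimens):
        sag = float(rng.uniform(8, 45))
        n_anchor = 1 + int(sag // 10)
        cx = 220 * 0.6 / 2
        anchors = tuple(
            (cx + rng.uniform(-28, 28), cx + rng.uniform(-28, 28), 6.0)
            for _ in range(n_anchor))
        truth = SceneTruth(seed=seed * 104_729 + i, shape=(220, 220),
                           well_radius=60.0, sag=sag, anchors=anchors)
        stack = synth_sheet_stack(truth)
        secs, vox = reslice_stack(
            stack, (truth.voxel_z, 0.6, 0.6), spacing=5.0)
        profiles = [trace_sheet(s, vox) for s in secs]
        mid = profiles[len(profiles) // 2]
        nsec, nz, nx = secs.shape
        x_um = (np.arange(nx) + 0.5) * 0.6
        H_total = (nz - 1) * truth.voxel_z
        sub = np.stack([
            well_substrate_height(truth, x_um,
                                  np.full(nx, k * 5.0 + 0.3), H_total - 3.0)
            for k in range(nsec)])
        st = anchor_density(secs, vox, profiles, sub)
        dh.append(mid.delta_h)
        dens.append(st.anchor_density)
    return correlate_dh_anchors(dh, dens)
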