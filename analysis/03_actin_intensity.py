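#!/usr/bin/env python
"""Recover a planted actin-intensity decay against the distance map.

Synthesizes a fiber-textured actin projection over the spheres substrate
whose local mean falls off as 1 + a*exp(-delta/lambda_I), then runs the
superpixel intensity pipeline: normalization, block means, binned
median/IQR versus delta, Spearman correlation, and an exponential fit
that should recover lambda_I.

Writes results/actin_intensity_vs_delta.csv and prints the fit.
"""

import numpy as np

from curvescape.intensity_quant import (
    intensity_vs_distance, normalize_intensity, rasterize_superpixels)
from curvescape.studies import recover_lambda_I, sphere_distance_scene
from curvescape.synthetic_data import SceneTruth, synth_actin_image

SEED = 1

spec, stack, dmap = sphere_distance_scene()
lam_true, lam_hat, n, rho = recover_lambda_I(SEED, dmap)
print(f"planted lambda_I = {lam_true} µm, recovered = {lam_hat:.1f} µm "
      f"({100 * abs(lam_hat - lam_true) / lam_true:.1f}% error) "
      f"over n = {n} superpixels")
print(f"Spearman r = {rho:.3f} (intensity falls with distance to "
      "concave-direction regions)")

truth = SceneTruth(seed=SEED, shape=dmap.delta.shape,
                   pixel_size=dmap.pixel_size)
img = synth_actin_image(truth, delta=dmap.delta)
raster = rasterize_superpixels(normalize_intensity(img), 12)
_, binned, _ = intensity_vs_distance(raster, dmap)
binned.to_csv("results/actin_intensity_vs_delta.csv", index=False)
print(f"binned median curve written ({len(binned)} delta bins of 2 µm); "
      f"first/last bin medians: {binned['median'].iloc[0]:.2f} -> "
      f"{binned['median'].iloc[-1]:.2f}")
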