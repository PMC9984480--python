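# Methods

`curvescape` reimplements, as a tested pipeline, the geometric design and
image-quantification computations used to measure curvature-guided
multicellular organization on microfabricated substrates: analytical
curvature fields of six substrate families, projected curvature and
distance maps at confocal resolution, actin-intensity and nuclei
statistics against those maps, FFT-based stress-fiber orientation,
cell-sheet detachment metrics, and mesh curvature estimation.  Raw
confocal data of this kind are typically only available on request, so
every stage is exercised end-to-end on synthetic fluorescence data with
known ground truth.

## Substrate geometry

All substrates are half-surfaces (π-revolutions, or half-tubes) standing
on a planar surround.  The sign convention is fixed by the biology-facing
reading: the normal points out of the substrate, and curvature is
positive where the surface bulges toward it, so a spherical protrusion
has κ1 = κ2 = +1/R, a spherical well −1/R, mean curvature
H = (κ1 + κ2)/2 and Gaussian curvature K = κ1κ2.  Curvatures are
non-dimensionalized by the design's sphere radius R = 180 µm × scale, so
the convex sphere maps to κ1 = κ2 = 1 and the constant-H cylinder
(radius R/2) to κ1 = 2.

Axisymmetric families are defined by an exact generatrix (axial a(t),
radial r(t)) with closed-form first and second parameter derivatives;
the revolved surface's principal curvatures follow from the
surface-of-revolution formulas

    κ_meridian = (a''r' − a'r'') / (a'² + r'²)^(3/2)
    κ_parallel = a' / (r √(a'² + r'²)),

so no finite differencing enters the design pipeline (an independent
finite-difference fundamental-form oracle appears only in the tests).

Family parametrizations and default shape parameters (all scale with the
design, reconstructions where the original constants are not public):

- **cylinder** — radius R/2 = 90 µm, chosen so H matches the sphere's
  (the constant-mean-curvature family cylinder–unduloid–spheres).
- **spheres** — semicircle string, radius 180 µm, period 360 µm; the
  touching poles are genuine pinches and are flagged, not interpolated.
- **unduloid** — exact Delaunay surface. From the first integral of the
  CMC equation, ρ/√(1+ρ'²) = Hρ² + c, the neck and bulge radii satisfy
  ρ_min + ρ_max = 1/H; defaults bulge 135 µm, neck 45 µm give H = 1/180
  µm⁻¹, equal to the sphere's. With ρ(u)² = a²sin²u + b²cos²u the axial
  coordinate obeys dz/du = (ab + ρ²)/ρ, integrated by fine-grid
  quadrature; curvatures use only analytic derivatives, so H is constant
  to machine precision. The axial period is the surface's natural one
  (≈ 418 µm): a true unduloid with the sphere's H cannot also have the
  sphere-string's 360 µm period, which is reached only in the degenerate
  sphere-string limit.
- **catenoids** — string of r = c·cosh(z/c) pieces, neck c = 60 µm,
  rim radius 180 µm, mirrored C⁰ joins at the rims; H = 0 exactly.
- **pseudospheres** — tractroid string, c = 90 µm (K = −1/c²
  everywhere), truncated at cusp radius 30 µm and at 87° below the rim:
  the tractroid's rim is a cuspidal edge with unbounded meridian
  curvature, so a printable design must stop short of it.
- **sinusoidal cylinder** — half-tube of radius 90 µm swept along
  x = A sin(2πy/λ) with A = 80 µm, λ = 720 µm (chosen to give a clearly
  bent, non-self-intersecting tube; A(2π/λ)²·r ≈ 0.55 < 1).  Curvatures
  from the tube-around-a-curve closed form: 1/r around the section and
  −k cosφ/(1 − rk cosφ) along the path, giving K = 0 over inflections
  and torus-consistent alternating signs across each bend (outer side of
  a bend elliptic, inner side saddle).

The concave (imprint) variant of any design negates both principal
curvatures (κ1 ← −κ2, κ2 ← −κ1), flipping H and preserving K; the
transform is an involution and keeps κ1 ≥ κ2.  Umbilic samples (spheres)
carry no principal directions and are masked, matching the exclusion of
spheres from alignment analysis.

## Projected maps and the distance transform

Maps are orthographic top views at 0.60 µm pixels (the confocal xy
resolution), with pixel centers at (i + 0.5)·pixel size.  Rasterization
is a z-buffer over densely sampled patch points; per pixel the sample of
largest |z| is kept, which selects the topmost point for a protrusion
and makes convex and concave variants of one design rasterize onto
bitwise-identical K maps.  Silhouette pixels therefore carry a sample
adjacent to the silhouette; for axisymmetric families this is exact
because curvature does not vary around the parallel.  Pinholes left by
sampling are closed morphologically and marked direction-undefined.

The curved-to-planar transition is assigned a fillet of radius 15 µm: a
band of that width in the flat surround receives a principal curvature
of magnitude 1/15 µm⁻¹, concave (κ2 < 0) at the foot of convex
substrates and convex (κ1 > 0) at the rim of concave wells — the sign
rule is our reconstruction from the local geometry of the fillet.  Sign
maps use a tolerance of 1e−3 in normalized units, far below any designed
nonzero curvature (smallest ≈ 0.9).

The distance map δ_{κ2<0} is the average of two exact Euclidean distance
transforms, distances in µm: to pixels with κ2 ≤ 0 and to pixels with
κ2 < 0.  Averaging weights strictly convex regions (κ2 > 0) above
developable ones (κ2 = 0), and δ = 0 wherever κ2 < 0.

## Intensity quantification

Projections are normalized to unit mean and downsampled into square
superpixels by block means; trailing partial blocks are dropped rather
than padded, since partial-block means would bias edges.  Frequency maps
normalize each image, sum across images, split the sum into periodic
units along the vertical axis and sum the units; the result is linear in
the inputs and permutation-invariant.  Intensity-versus-sign comparisons
draw a seeded sample (default 100 per category, without replacement)
feeding a two-sided Mann–Whitney U; intensity-versus-δ uses 2 µm bins
for the median/IQR curve (a display choice; the correlation itself is
Spearman's r on the unbinned superpixel pairs).  ROI comparisons divide
each ROI mean by the grand mean of all ROI means within the same image.

## Nuclei

Segmentation order is fixed: threshold (Otsu by default, manual
override retained) → binarize → fill small holes → watershed split →
morphological opening (disc of radius 1 px).  Watershed markers are
h-maxima of the distance transform (h = 2 px).  Fragments below 15% of
the median area of the *pre-filter* label set are discarded, once; the
pre-filter median is stored so the rule is auditable and idempotent.

Frequency maps wrap centroids into one periodic unit, build a 100 × 100
histogram and convolve with a 3 × 3 Gaussian kernel (σ = 1.5 bins,
normalized to unit sum, zero-padded), conserving interior mass.  Maps
always combine at least three specimens; under a uniform null the
expected coefficient of variation across bins is √(Σk²/μ) ≈ 0.195 at
three specimens of 10⁴ centroids (Σk² ≈ 0.114 for this kernel) — a
single specimen necessarily sits near 0.34, which is why the flatness
check is defined on the combined map.

Density versus δ divides the centroid count per δ bin by the number of
substrate pixels in that bin (area normalization); empty bins are
omitted because sparse far-δ bins otherwise spike artificially.  The
overlay is a cubic smoothing spline with GCV-selected penalty
(`scipy.interpolate.make_smoothing_spline`).

## Stress-fiber orientation and alignment

Tiles (80 × 80 px by default) are Hann-windowed and their FFT power
spectrum is accumulated into 1° angular sectors over a radial band of
wavelengths between 4 px and half the tile, weighted by f²: broadband
fiber spectra concentrate power at low frequencies where angular
selectivity is poor, and the f² weight restores balance (it improved
fiber-texture recovery from ≈7° to ≈1.5° RMS without affecting stripe
accuracy).  The dominant band angle starts at the full-profile circular
mean (on doubled angles) and is refined by a ±30° windowed circular
mean (three mean-shift iterations), so a dominant band wins over
secondary ones; the image orientation is the band angle + 90°.
Confidence is the resultant length of the angular profile; tiles below
0.35 are undefined — calibrated so that isotropic white-noise nulls
(max ≈ 0.25 over 500 tiles) never pass while fiber textures (≥ 0.85)
and stripes at SNR 1 (≈ 0.7) always do.  Angles are degrees from the
image horizontal in array coordinates, undirected, in [0, 180).

The degree of alignment with the κ2 principal direction is
DA = 1 − ∠(sf, pd)/90 with the acute difference of undirected angles;
DA = 1 along the κ2 direction and DA = 0 along κ1 (the directions are
orthogonal).  Angle/DA distributions use an Epanechnikov-kernel density
estimate with wraparound (angles) or boundary reflection (DA), so the
density integrates to one by construction.  A Hessian-eigenvalue ridge
detector (skeletonized, segments oriented by PCA) corroborates the FFT
angles on fiber subpopulations.

## Cell-sheet detachment

Z-stacks are resliced into x–z sections every 5 µm along y (linear
interpolation).  The sheet trace takes the topmost supra-threshold voxel
per column of the middle section; interior gaps longer than 2 columns
mark the sheet as non-spanning (partial sheets with holes), in which
case Δh is undefined rather than extrapolated.  Δh is the maximum
vertical deviation of the traced polyline from the chord through its
endpoints; it is invariant to intensity scaling and lateral translation
by construction.  Anchor density binarizes the stack (Otsu per stack by
default) and counts positive voxels in the region strictly between the
traced sheet and the substrate surface — taken from the substrate design,
not from imaging — excluding a margin (default twice the z voxel) next
to both, whose brightness belongs to sheet and shell, not anchors.
Spearman's Δh–anchor correlation uses an exact permutation p-value for
n ≤ 9 and the asymptotic one otherwise.

## Mesh curvature

For each vertex, vertices within a Euclidean ball of radius
r = 20⟨e⟩ (⟨e⟩ the mean edge length) are expressed in a frame aligned
with the area-weighted vertex normal and fitted with
z = ax² + bxy + cy² + dx + ey; the linear terms absorb normal-estimate
error, and K and H come from the fitted fundamental forms at the
origin.  Rank-deficient neighborhoods are flagged NaN.  The fit bias
grows as (r/R_feature)², so validation meshes are chosen dense enough
that r stays well below the feature radius (icosphere with 163 k
vertices for the 5% sphere check; 393 k-vertex torus for the sign
pattern); evaluation subsamples vertices and caps neighborhood size
(seeded) to keep dense meshes tractable without changing the
estimator's locality.  "Area-normalized" curvature is interpreted as
K̃ = K × total surface area — a scale-free convention (K̃ is invariant
under uniform scaling, estimator included) suitable for comparing
curvature spectra across differently sized shapes; the precise
normalization used in the original mesh-processing chain is not public,
so this convention is an explicit assumption of the package.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not the optics: actin projections are sums of Gaussian-profile
filaments (length 30 µm, width 1.2 µm, density 0.02 µm⁻², jitter 5°)
following a planted per-superpixel angle field, with local mean
modulated by 1 + a·exp(−δ/λ_I) (defaults a = 1.5, λ_I = 40 µm); nuclei
are rotated ellipses with full axes 8–14 µm placed by rejection
sampling from exp(−δ/λ_n) (default 40 µm); sheet stacks contain a
bright shell along a concave spherical well, a paraboloid-cap sheet
whose center sag equals the planted Δh, and cylindrical anchor bridges;
meshes carry closed-form K where available.  Noise is Poisson (gain 50)
plus Gaussian read noise (σ = 0.05); images default to 1024 × 1024 px
at 0.60 µm.  Scenes are bit-reproducible: one scene seed spawns fixed
per-operation substreams (numpy `SeedSequence`), so adding a generator
never perturbs existing scenes.

What the generator does *not* emulate — point-spread blurring beyond a
1 px Gaussian, spectral bleed-through, cell bodies and cytoplasmic
background, fiber curvature, nucleus clustering and overlap textures —
bounds what green tests mean: they certify the quantification chain
(given data with the assumed structure, parameters are recovered), not
robustness to every optical artifact of real confocal stacks.

## Problem sizes and numerical choices

The shipped studies use a two-period spheres substrate rasterized at
0.60 µm (1300 × 700 px), ≈ 6 300 superpixels of 12 px for the λ_I fit,
5 000 nuclei for the λ_n fit, 100 tiles for orientation calibration,
10 specimens for the Δh–anchor cohort, and the mesh resolutions listed
above — sizes at which every recovered parameter sits comfortably inside
its tolerance while a full run of drivers, tests and acceptance script
completes in minutes on one CPU.  Curvature identities are asserted to
1e−12 (algebraic), analytic-versus-oracle agreement to 1e−4 on refined
grids, and EDT against brute force exactly.

## Known limitations

- The exact shape constants of the original substrate designs
  (unduloid interpolation parameter, catenoid neck, pseudosphere scale,
  sinusoid amplitude/wavelength) are not public; the defaults above are
  reconstructions, overridable per `SubstrateSpec.param_overrides`.
- The transition-band sign rule and the K̃ = K·A normalization are
  documented reconstructions of underspecified steps.
- The published Δh–anchor correlations on real stacks (r ≈ 0.7–0.8)
  cannot be recomputed without the raw data; the pipeline is instead
  validated by sign/magnitude recovery on simulated cohorts.
- `register_roi` handles axis-aligned ROIs (with 90° reorientation);
  arbitrary-angle ROI rotation is out of scope.
- Sub-sheet anchor masking assumes the substrate geometry is known from
  the design; it is not estimated from the image stack.
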