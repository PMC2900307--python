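# Methods

`nucpattern` tests whether point-like nuclear compartments — centromeric
spots in rabbit embryo and mammary-gland nuclei, DAPI-bright chromocenters
in *Arabidopsis thaliana* — are randomly, regularly or clusteredly arranged
inside individually shaped 3D nuclei imaged by confocal microscopy.  This
note documents the model, the estimators, the tunable parameters and their
defaults, the numerical choices, and what the synthetic phantoms do and do
not establish.

## The statistical model

Each nucleus is treated as a bounded, arbitrarily shaped 3D domain `W`
(its binary mask) containing a finite point pattern: the centres of gravity
of the detected compartments, with, for chromocenters, their equivalent
spherical radii.  Nuclei vary in size and shape and have no landmarks that
would support registration, so no pooling across nuclei is attempted at the
level of distances.  Instead, each nucleus serves as its own reference: the
observed pattern is compared with completely random binomial point patterns
(CRBPP) — the same number of points placed uniformly and independently in
the same nucleus.

Two cumulative distance functions quantify a pattern:

* **G** (nearest-neighbour): `G(x) = P(distance from a typical pattern point
  to its nearest neighbour <= x)`, estimated from the k observed
  nearest-neighbour distances.
* **F** (empty space): `F(y) = P(distance from a uniform random position in
  W to the nearest pattern point <= y)`, i.e. the fraction of the nuclear
  volume within `y` of the pattern.  It is estimated stochastically from
  `N_E` uniform evaluation points (default 10 000, enough to make the
  evaluation-sampling noise negligible), which preserves the subvoxel
  precision of the centres of gravity.

No edge correction is applied: compartments cannot exist outside the
nucleus, so the usual corrections for unobserved points would only discard
data and bias the estimates.

For a regular (mutually repulsive) pattern the empty-space distances are
short and uniform — F rises earlier and more steeply than under CRBPP —
while nearest-neighbour distances are long — G rises later.  Clustered
patterns behave oppositely.

## The spatial distribution index (SDI)

For one nucleus with k observed points:

1. Simulate `P1` CRBPP patterns of k points; average their distance
   functions on a common radius grid to get the Monte-Carlo reference `F0`
   (or `G0`).
2. Simulate a second, independent set of `P2` patterns; for each, record the
   *signed difference of maximum amplitude* `D_i = (F_i - F0)(y*)`,
   `y* = argmax |F_i - F0|`.  Using a fresh set avoids under-estimating the
   null fluctuations (the first set already shaped `F0`).
3. Compute the observed deviation `D_obs` the same way and rank it:
   `SDI = (#{D_i >= D_obs} + 1) / (P2 + 1)`.

The SDI is an exact Monte-Carlo p-value: under CRBPP it is uniform on
`{1/(P2+1), …, 1}`, regardless of nuclear size or shape — this implicit
normalization is what lets very different nuclei be combined.  Under the
F-function, regular patterns give `D_obs` large and positive, hence SDI near
its floor `1/(P2+1)`; clustered patterns give SDI near 1.  The directions
reverse for G.  The `(x+1)/(P2+1)` convention (observed pattern counted in
its own null set) guarantees a positive index and exact uniformity; the
literal `x/P2` variant is available via `AnalysisConfig.include_observed`.

At the population level, n per-nucleus SDIs are tested against Uniform(0, 1)
with the two-sided one-sample Kolmogorov–Smirnov test (`alpha = 0.05`).
Working with the full SDI distribution rather than binarizing per-nucleus
decisions preserves sensitivity to weak departures.  Kendall's tau-b (exact
p-value for small n) tests whether SDI correlates with nuclear flatness
among nuclei whose minor axis is Z-oriented, which would indicate that
slide-induced flattening, not biology, drives the regularity.

**Hardcore null for chromocenters.**  Chromocenters have non-negligible
size, so their null assigns each simulated point the radius of one observed
chromocenter (randomly permuted per replicate) and requires (a) that
distance to the nuclear envelope and (b) no overlap between spheres —
pairwise centre distance at least `r_i + r_j`.  The literal single-radius
exclusion (`max(r_i, r_j)`) is available through
`AnalysisConfig.hardcore_rule = "max"`.  Sampling is sequential rejection
with a budget of 10⁵ rejections, after which packing is declared infeasible.

## Estimator implementation details

* All geometry is computed in physical micrometres; voxel `(i, j, k)` is
  centred at `(i·sx, j·sy, k·sz)`, so XY–Z anisotropy is handled once.
* Uniform sampling in a mask draws a foreground voxel uniformly, then a
  continuous offset inside it — exactly uniform over the voxelized domain
  with subvoxel precision.
* The `N_E` evaluation points of one nucleus are drawn once and shared by
  the observed pattern and all its Monte-Carlo replicates.  This mirrors
  the estimation protocol (evaluation points are generated per nucleus),
  removes one noise source from the observed-vs-simulated comparison, and
  makes the per-nucleus cost `O((P1+P2)·k·N_E)` instead of quadratic in the
  evaluation-point budget.
* Observed and simulated functions are evaluated on a common grid of 512
  radii spanning 0 to the mask bounding-box diagonal.  Nearest-point
  distances are computed by a blocked squared-distance expansion in float32
  (distances only feed ~µm-wide CDF bins, so single precision is ample);
  binning uses direct division on the uniform grid.  Deviation ties across
  radii break at the smallest radius.
* An independent F estimator (`f_function_edm_oracle`) computes the
  anisotropy-aware Euclidean distance map from the pattern points rounded
  to voxels and takes the normalized cumulative histogram over the nucleus.
  It loses subvoxel precision and serves as a cross-check of the stochastic
  estimator, not as the production path.
* Reproducibility: every stochastic function takes a `numpy.random.Generator`
  (or derives one from `AnalysisConfig.seed`); one seed yields bit-identical
  SDI tables.

## Segmentation

**Nuclei.**  Three recipes match the three labeling regimes.
(1) *HP1β, embryo stacks*: median (radius 1 voxel) and Gaussian (sigma = 2
XY voxels, Z scaled by the spacing ratio) denoising; gradient-weighted mean
threshold (RATS, `t = Σ I·|∇G I| / Σ |∇G I|`), which is invariant to
boundary blur and equivariant under affine intensity rescaling; watershed on
the anisotropy-aware distance map to split touching nuclei, seeded by
h-maxima (default h = two z-voxels) to avoid over-splitting from surface
bumpiness; removal of border-truncated nuclei and of objects under
200 µm³.
(2) *DAPI, mammary tissue*: rim-dominated signal is manually thresholded,
closed with a round kernel (default 1 µm ball, anisotropic in voxels) to
bridge rim gaps, hole-filled, and watershed-separated; cell-type selection
stays with the caller.  A closing kernel much larger than the rim thickness
can fail to seal holes in very thin rims — the kernel should be on the
order of the gap, not of the nucleus.
(3) *DAPI, single plant nuclei*: the stack is cropped to the nucleus
bounding box, an isodata threshold is computed, and — because isodata is
biased upward on background-dominated images of internally heterogeneous
nuclei — the final threshold is lowered to `m - 2s`, the mean minus twice
the standard deviation of intensities over the preliminary foreground
(applied once, not iterated).  Hole filling, opening and closing (1-voxel
radii) regularize the mask; the largest component is kept.

The nuclear envelope is triangulated by marching cubes at level 0.5 on the
binary field smoothed with a 1-voxel Gaussian — the smoothing removes most
of the staircase-area bias (a digitized r = 20-voxel sphere scores
compactness ≥ 0.95 instead of ~0.85 raw); for masks so small that smoothing
would erase them, the raw binary field is contoured.

**Centromeric spots.**  Median + Gaussian (sigma 0.07 µm) denoising, then a
white top-hat by size: subtraction of a grayscale area opening with a volume
criterion (default 0.2 µm³ ≈ 10× the spot core), which removes any structure
larger than the criterion while leaving diffraction-limited spots intact.
Because the PSF elongates spots along Z beyond the mask, masking uses a
2-voxel dilated mask.  Objects strictly smaller than 0.02 µm³ are removed.
Two thresholding rules: the embryo rule scans integer thresholds from 1
upward and stops at the first count ≤ 44 (the rabbit chromosome number),
with the minimum-volume filter applied inside the loop so the bound refers
to countable final objects; the mammary rule thresholds at the median of
the 11 brightest 26-connected regional maxima divided by 4 (all available
maxima are used when fewer than 11 exist).  Regions are reduced to
intensity-weighted centres of gravity (binary centroids via a flag);
centres up to one voxel outside the mask are clipped to the nearest
foreground voxel.

**Chromocenters.**  A gradient watershed partitions the nucleus (Gaussian
gradient, sigma 2 XY voxels; gradient minima shallower than 1% of the
nuclear intensity range are suppressed before flooding to curb noise-driven
over-segmentation).  Each region's value is the mean intensity in a
0.15 µm ball around its barycentre.  Adjacent regions whose values differ
by less than a threshold (default 10% of the nuclear intensity range) are
merged smallest-difference-first, with deterministic label-id tie-breaks;
merged values are size-weighted means.  One pass of grayscale closing on
the region adjacency graph (min over neighbours of max over neighbours,
self included) raises dark basins such as the nucleolus so they stop
inflating their neighbours' contrast.  Each region is scored by
`contrast × compactness`, where contrast is the size-weighted mean value
difference to the neighbours and compactness is `36πV²/S³` of the region
itself (clipped at 1).  A threshold on this index — a parameter replacing
an interactive step; `index_spectrum` lists the sorted indices to guide the
choice — extracts the chromocenters, and a label exclusion list supports
removal of visually identified false positives.  Each chromocenter
contributes its centre of gravity and equivalent spherical radius
`(3V/4π)^{1/3}`.

## Morphometry

Volume is the voxel count times the voxel volume (exact for the voxelized
mask).  Surface area comes from the marching-cubes mesh above.  Compactness
is `36πV²/S³`: 1.0 for a sphere (by construction, to 1e-12 from the
closed-form V and S), `π/6 ≈ 0.524` for a cube, decreasing with surface
irregularity, scale-invariant.  Principal axes derive from the covariance
of foreground voxel coordinates; axis lengths are reported as the full axes
of the equivalent uniform ellipsoid, `2·sqrt(5λ)` (a uniform solid
ellipsoid of semi-axis a has coordinate variance a²/5).  Flatness is
`L_mid/L_short`, elongation `L_long/L_mid`; both are invariant to the axis
length constant, to uniform scaling and to rigid rotation.  The main
flattening (elongation) direction is the frame axis with the largest
absolute cosine against the shortest (longest) principal axis, ties
breaking toward the earlier axis in (X, Y, Z).  Volume moments were chosen
over mesh-vertex covariance for noise robustness; `principal_axes` operates
on the mask directly so either surface could be substituted.

## Synthetic data

The generator (`synthetic_data`) renders ground-truthed stacks emulating
the three imaged systems: ellipsoidal, invaginated (ellipsoid minus 1–3
spherical lobes) and elongated (elongation ≈ 2.6) nuclear masks at confocal
spacings (XY 0.04–0.1 µm, Z 0.122–0.24 µm); CRBPP, hardcore and
parent–offspring cluster patterns; a nuclear channel (optionally
rim-weighted to mimic peripheral DAPI, with ellipsoidal chromocenter bodies
when radii are present) and a spot channel of anisotropic Gaussians
(default PSF sigma 0.1/0.1/0.3 µm, reproducing the Z elongation that pushes
spot tails outside the mask) over a constant background with additive
Gaussian noise (Poisson optional).  Default intensities (amplitude 200,
background 20, noise sigma 4) give the SNR regime in which the detection
recipes are expected to be near-perfect.

`well_separated_pattern` places spots with a minimum pairwise separation in
PSF-normalized coordinates (each axis divided by its PSF sigma, default 7
sigmas) plus an envelope margin.  Whether two rendered Gaussian spots merge
into one connected component at low thresholds depends on their separation
in sigmas, not in µm, so an isotropic µm hardcore cannot guarantee
resolvability along Z; this generator defines "well separated" accordingly
and is used for the 44-spot phantom.

What the phantoms do not emulate: chromatin texture, depth-dependent
attenuation, realistic optics beyond a Gaussian PSF, nucleoli in the
simulation null, or segmentation errors correlated across nuclei.  Passing
the phantom suites therefore validates the estimators and the pipeline
plumbing, not the biological conclusions on real images.

## Study-scale checks and problem sizes

The acceptance script (`scripts/acceptance.py`) recomputes three quantities
from scratch; sizes were chosen as the smallest at which the quantities are
stable:

* **Null calibration** — 200 populations × 40 ellipsoidal nuclei (semi-axes
  uniform in 3–6 µm, spacing 0.1/0.1/0.24 µm) × 20 CRBPP points, F-SDI with
  `P1 = P2 = 100`, `N_E = 2000`; fraction of populations where the KS test
  rejects at 5%.  Expected: the nominal 5% within the ±3-point binomial
  band.
* **Compactness normalization** — closed-form sphere compactness (exactly 1).
* **Count-constrained search** — the 44-spot phantom above; the incremental
  threshold search must return at most 44 objects and finds exactly 44 at
  this SNR.

The test suite additionally verifies the estimator cross-check (Monte-Carlo
F vs EDM histogram within 0.02 sup-distance on 20 seeded instances with
pattern points on voxel centres, so both estimators target the same
discretized quantity), the monotone response of the median F-SDI to an
increasing hardcore radius (0/0.3/0.6/0.9 µm, k = 15, 5 µm nucleus, 50
nuclei per rung), the direction contract for clustered patterns (median
F-SDI > 0.9, median G-SDI < 0.1), closed-form morphometry and rank
statistics, and bit-identical reproducibility under a fixed seed.

## Known limitations

* The hardcore rejection sampler is sequential (no dynamic reallocation);
  dense packings that a smarter sampler could realize may be reported
  infeasible.
* The SDI's discrete support (granularity `1/(P2+1)`) adds a small bias to
  the KS statistic for very small `P2`; with `P2 ≥ 100` and population
  sizes ≤ 100 the effect is well inside the binomial tolerance of the
  calibration check.
* Region compactness for few-voxel watershed regions is noisy; the
  shape/contrast index should not be interpreted quantitatively for regions
  under ~30 voxels.
* The EDM-based F estimator degrades with coarse voxels relative to
  inter-point distances; it is a cross-check, not a substitute for the
  stochastic estimator.
* Nucleolus-occupied volume is not excluded from the CRBPP null; on real
  nuclei with large nucleoli this biases the analysis toward apparent
  clustering, so a regularity finding is conservative in that respect.
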