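# Methods

This note documents the models, conventions and numerical choices behind
`cereplaq`, and what the synthetic phantoms do and do not establish about
the analysis of real tomographic data.

## Coordinate and angle conventions

Grid axes map to anatomy as axis 0 = dorso-ventral (DV), axis 1 =
medio-lateral (ML), axis 2 = anterior-posterior (AP); axis 2 therefore
indexes coronal slices, matching tomographic reconstructions whose
reconstruction plane coincides with the coronal plane. Voxel indices are
0-based; physical positions refer to voxel centres,
`(i + ½) · voxel_size`. The default voxel size is 1.625 µm, isotropic.

For a unit axis `(v_DV, v_ML, v_AP)`, azimuth = `atan2(v_ML, v_DV)` in
(−180°, 180°] and elevation = `asin(v_AP)` in [−90°, 90°]. Vectors in the
coronal plane have elevation 0; vectors in the transverse plane have
azimuth ±90°. A plaque axis is undirected: all statistics compare axes
through `|a·b|`, and azimuth–elevation histograms count both antipodal
representations of every axis, which is why clustered axial data always
show paired clusters (at (az, el) and (az ± 180°, −el)). Elevation is kept
in [−90°, 90°]; an elevation range of ±180° is not producible under this
convention and is treated as a plotting artifact of sign-ambiguous axes.

## Plaque segmentation

Each seed (an in-plane circle plus an inclusive coronal slice range)
defines a cylindrical VOI; overlapping cylinders union. The gray histogram
of all VOI voxels (256 bins over the VOI gray range, smoothed by a 5-bin
moving average) is searched for peaks with prominence ≥ 1% of the maximum
count; the histogram is zero-padded so a peak sitting on the gray range
boundary is still detected. The two most prominent peaks are taken as
tissue background (lower gray) and plaque (higher gray), and the threshold
is the gray value of the minimum count between them — on ties, the
midpoint of the minimal plateau. Two guards handle degenerate histograms:
bimodality is only accepted when the valley dips below 75% of the weaker
peak (pure sampling wiggles on a unimodal histogram otherwise pass the
prominence filter), and when no valid pair is found the threshold falls
back to Otsu's method with a diagnostic flag. The choice of the *valley*
(rather than, e.g., the midpoint of the two peak positions) is a design
decision and is always reported in the threshold diagnostics.

Foreground is strict (`gray > threshold`), components are 26-connected by
default (6 available in config), and components with physical volume
`≤ 150 µm³` (strict) are discarded; at 1.625 µm voxels this keeps objects
of ≥ 35 voxels. Surviving labels are renumbered 1.. in order of descending
volume. Strict inequalities make object counts exactly reproducible.

## Surface area and sphericity

Sphericity is `S = π^(1/3) (6V)^(2/3) / A`: the surface area of the sphere
with the region's volume divided by the region's measured surface area.
`V` is voxel count × voxel volume. `A` is the consequential choice. Two
naive estimators fail: counting exposed voxel faces overestimates a
sphere's area by ~50%, and triangulating the raw binary mask's level-0.5
iso-surface (marching cubes) still overestimates by ~9% at *any* radius,
because the staircase never vanishes in physical units — both would push
every sphericity far below its continuum value. Smoothing the mask before
meshing removes the staircase but introduces a curvature pullback of order
σ²/r that inflates `S` of voxel-scale objects (a median 10³ µm³ plaque has
a minor radius of ~3 voxels) above 1.2.

The estimator used is therefore the **coarea gradient integral**:
`A = ∫ |∇(G_σ ∗ χ)| dV`, where `χ` is the mask indicator and `G_σ` a
Gaussian with `σ = clip(inradius/8, 0.5, 1.2)` voxels (inradius from the
Euclidean distance transform). The coarea formula equals the iso-surface
area *averaged over all levels*, which cancels most of the single-level
curvature bias while the smoothing suppresses the staircase. Measured
accuracy: digitized spheres of radius 10/20/40 voxels give
S = 1.015 / 1.003 / 0.9996 (monotone convergence to 1); a digitized
(2, 1, 1) prolate spheroid gives 0.933 vs the exact 0.929; small prolates
with minor radius ≥ 2 voxels are within 0.03; rotating a generating
ellipsoid by 45° moves S by < 10⁻³. Below ~2 voxels inradius the area is
underestimated and S may exceed 1; values > 1 are flagged
(`sphericity_flag`), never clamped. Marching cubes on the smoothed mask is
retained (`method="mesh"`) as an independent cross-check.

## Orientation

The principal axis is the eigenvector of the largest eigenvalue of the
3×3 second central moment matrix of the object's voxel centres (unweighted
binary mask; a gray-weighted variant would change moments by < the
digitization noise for the high-contrast objects considered here). The
reported sign makes the largest-magnitude component positive — reporting
only; all statistics are sign-blind. When the relative gap between the two
largest eigenvalues is < 10⁻⁶ the orientation is flagged undefined (a
digitized sphere centred on a lattice point has exactly degenerate
moments). Orientation analysis is restricted to records with
`S < S̄ + σ_S` (strict): near-spheres have no meaningful main axis, and
under Gaussian sphericities this retains a fraction Φ(1) ≈ 0.84.

Region populations are summarized by the orientation tensor
`T = (1/n) Σ aᵢaᵢᵀ`; its principal eigenvector is the undirected mean
axis. Cone "semi-angles" are operationalized as the 50th/90th percentiles
of the deviations `δᵢ = arccos |aᵢ·mean|`, overall and after projecting
the axes into named coordinate planes (transverse and coronal by default)
— percentiles, because an envelope of noisy axial data is not a stable
statistic. The 2D histogram uses 10° bins in both angles (config).

## Purkinje detection

Blobness per scale `s ∈ {6, 8, 10, 12} µm` (soma radius range): Gaussian
smoothing at `s`, scale-normalized Hessian (second derivatives × σ² in
voxel units), closed-form trigonometric eigenvalues of the symmetric 3×3
matrix (vectorized; magnitude ties broken by signed value ascending),
response `B = (|λ₁|/|λ₃|)(1 − exp(−Σλ²/2c²))` for all-negative
eigenvalues, else 0, with `c` = half the maximum Hessian Frobenius norm at
that scale; per-voxel maximum over scales. Two degeneracy guards: a
constant volume returns zero everywhere, and a scale whose maximum
Frobenius norm is at rounding-noise level (≤ 10⁻⁸ × gray range × σ²) is
skipped — otherwise `c` would normalize pure float noise to an O(1)
response. Measured discrimination on equal-contrast 10 µm-radius test
solids: sphere peak ≈ 0.86, tube and plate peaks < 10⁻³.

Detection applies hysteresis thresholding: voxels with `B ≥ 0.5` seed the
detection and grow into their 26-connected support region `B ≥ 0.1`
(threshold/5). The high-blobness core of a sphere is its inner part only —
raw seed components of true 15–25 µm somata measure just 3–12 µm
equivalent diameter — while the support region tracks the soma extent
(12–23 µm measured on phantoms). Components are then filtered by
equivalent-sphere diameter (default 12–30 µm) and labelled in order of
descending peak blobness. An optional mask can confine the search to the
interface band; it is off by default because nothing requires the real
analysis to have been restricted that way.

## Statistics

Scalar summaries use the sample standard deviation (n−1) and the adjusted
Fisher–Pearson skewness; a zero-variance sample reports skewness 0 with a
flag. Log-normality of plaque volumes is quantified as the KS distance
between the log-volumes and the Gaussian with the *same* mean and SD —
moment-matched by construction, mirroring the visual-overlay construction
this comparison classically uses, not an MLE fit; the overlay data
(area-normalized histogram plus reference density) is reported alongside
the statistic. Group sphericity differences use a two-sided Mann–Whitney U
— sphericity is bounded and skewed, so a rank test is preferred over a
t-test, and no particular test is canonical for this comparison; for two
groups of ≤ 8 the p-value is exact enumeration of all label arrangements
with midranks (deterministic, tie-corrected; identical groups give p = 1
exactly), otherwise the tie-corrected normal approximation.

## The phantom: what it emulates, and what it does not

The generator renders, in order: three flat layers stacked along DV
(white 80 / granular 140 / molecular 100 gray, 60 + 60 µm thick by
default) warped by a single sinusoid (amplitude 15 µm, period 200 µm) as a
minimal folium stand-in; somata (15–25 µm diameter, gray 190) centred on
the granular–molecular interface; capsule vessels (radius 2–4 µm, length
80 µm, gray 170) running in the coronal plane within the molecular layer;
prolate plaques (corona gray 160, concentric core gray 200 at 15% of the
volume) confined to the molecular layer; then additive Gaussian noise
(σ = 4).

Plaque volumes are log-normal with median 10³ µm³ and log-SD 1.256 — the
pair that simultaneously places 50% of volumes below 10³ µm³ and 90%
below 5·10³ µm³ — truncated at 2·10⁴ µm³ (the largest plaque volume such
tissue shows; untruncated tail draws would exceed the molecular layer's
thickness). Aspect ratios are uniform on 1.5–3.5, a free choice with no
published measurement behind it, picked so the digitized sphericities
spread over roughly 0.8–0.95. The default two-region layout assigns the
left half of the ML extent to "hemisphere" (preferred axis DV, isotropic
30° cone, sampled uniformly on the spherical cap) and the right half to
"vermis" (preferred axis ML, anisotropic spread: independent uniform
tangent tilts of ±60° within the transverse plane and ±30° out of it).

Placement is rejection sampling (200 retries per object, then an error
naming the object class — silent overlap would corrupt the ground truth)
against an occupancy grid with a 5 µm margin. Somata and vessels are
placed before plaques, and each plaque additionally keeps an inflated copy
of its own future VOI cylinder (footprint + 8 µm clearance) free of them:
this guarantees that no foreign bright object intrudes into any VOI, the
phantom counterpart of the observation that stray bright structures do not
contaminate intensity-based plaque segmentation. Two plaques may sit near
each other; they remain separate components. Sequential placement jams
near ~30% interface coverage, so dense soma populations need
proportionally larger grids.

Deliberately **not** modelled: phase-contrast image formation (fringes,
ring artifacts — assumed handled upstream in reconstruction), real folium
topology, vascular network topology, plaque sub-structure beyond the
two-level core/corona, and spatially correlated noise. Consequently,
passing the phantom suites shows that the pipeline recovers the generating
parameters under the geometry and contrast structure it assumes — clean
bimodal histograms, ellipsoidal plaques, spherical somata. On real data
the histogram valley is shallower, plaques are irregular, and measured
sphericities carry the surface-estimator bias discussed above; phantom
recovery rates are upper bounds, not predictions.

## Problem sizes and reproducibility

The test suites run phantoms at 96³–144³ (unit and property tests), 256³
for the two-region orientation-recovery study (110 plaques, the full
segmentation → morphometry → statistics chain) and 160×256² for the
plaque-vs-soma sphericity comparison (70 plaques, 60 somata) — sizes at
which every recovery statistic is stable across seeds while a full run of
the suite stays in the minutes range on one CPU. All randomness flows from
integer seeds through `numpy.random.default_rng`; the pipeline fans its
global seed out to per-stage seeds by hashing the stage name, and a run
manifest records the config hash, seed, versions, stage timings and SHA-256
checksums of every output (`verify_manifest` re-hashes them).

## Known limitations

- Sphericity of objects with inradius < ~2 voxels is biased upward and
  only flagged, not corrected; the 150 µm³ volume filter removes the worst
  cases but small retained plaques still carry a few percent of bias.
- The valley threshold assumes one background population inside the VOIs;
  seeds spanning regions of very different background gray (e.g. granular
  vs molecular) would blur the background peak.
- The blobness support threshold (threshold/5) sets measured soma extent;
  strongly overlapping somata can merge into one component and be lost to
  the diameter filter.
- Mann–Whitney exact enumeration is limited to both n ≤ 8 by design;
  beyond that the normal approximation is used even under heavy ties.
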