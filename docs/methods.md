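# Methods

This note documents the models, parameters and numerical choices behind
`thmorph`, and what the phantom-based validation does and does not show.

## Coordinate and sampling conventions

Arrays are ordered `(z, y, x)`, 0-based; voxel `i` along an axis with
spacing `s` occupies the half-open physical interval `[i·s, (i+1)·s)` µm and
all geometric predicates (cuboid membership, sphere membership, slab
membership) are evaluated at the voxel center `(i + 0.5)·s`. The
rostro-caudal axis defaults to array `y` with rostral at the low index; both
the axis and its direction are metadata on every volume and are honored by
every operation. The default sampling is the light-sheet protocol the
pipeline targets: 7 µm z-step between horizontal-section planes, 5 µm
in-plane. Nothing is ever resampled to isotropic voxels — shape
descriptors, sphere geometry, and distances are all computed in µm on the
anisotropic grid, which avoids interpolation artifacts in counting.

At this sampling a 12 µm ball contains only five voxel centers (a
plus-shaped set in one z-plane). Several defaults below are explicitly
chosen for this coarse-sampling regime and are all exposed in
configuration.

## Phantom model

The generator emulates the structural classes the morphometry quantifies,
with exact ground truth keyed to a seed:

- **Somata** — spheres (default Ø 12 ± 1 µm, intensity 200 ± 20) placed by
  rejection sampling inside ellipsoidal nucleus envelopes shrunk by one
  soma radius, with a minimum center separation (default 14 µm) and a
  clearance margin from vessel surfaces (default 10 µm). Placement is
  capped at 10,000 attempts per nucleus and fails loudly naming the
  nucleus; random sequential placement of hard spheres jams near 38%
  volume fill, and the stock layouts stay well below that.
- **Fascicles** — tubes (default Ø 10–14 µm, intensity 170) along smooth
  centerlines strictly monotone in the rostro-caudal coordinate, so each
  fascicle crosses any interior coronal plane exactly once. With
  `min_fascicle_separation_um` set (default 12 µm) the centerlines occupy
  evenly spaced mediolateral lanes with bounded wobble, guaranteeing
  pairwise disjoint fascicle surfaces — the regime used for exactness
  checks; with it unset, lateral offsets are Gaussian with `spread_um`,
  which emulates defasciculation.
- **Dispersed fibers** — thin (Ø 4 µm, intensity 90) short tubes scattered
  around the tract. After realistic blur they fall below any usable
  threshold: single neurites are invisible in this imaging regime, by
  design, and the pipeline never claims to count them.
- **Vessels** — long straight bright tubes (default Ø 10 × 220 µm,
  intensity 180) anchored at nucleus centers with random orientation;
  length ≥ 5 × diameter keeps the shape-based exclusion well-posed.
  `render=False` places the vessels (so soma placement is constrained
  identically) without painting them — the matched vessel-free
  counterfactual used to demonstrate that vessel signal does not leak into
  counts.
- **Optics** — anisotropic Gaussian blur with physical sigmas divided by
  the per-axis spacing; default σ = (3, 2, 2) µm (z, y, x), i.e., an axial
  FWHM comparable to the 7 µm z-step. Blur conserves total intensity for
  interior structures to well under 1%.
- **Noise** — constant background (default 20) plus shot noise in the
  Gaussian approximation, sd = √(signal/scale) with `poisson_scale` = 0.5
  photons per intensity unit, plus additive read noise (sd 4). The two
  standard-normal fields are drawn from fixed children of the seed,
  independently of the signal, so a local change to one structure perturbs
  only local voxels — a property the vessel-counterfactual comparisons
  rely on, and a faithful approximation in the ≥10-photon regime these
  defaults produce.

Determinism: identical `PhantomSpec` (including seed) gives bit-identical
volumes and ground truth; every structure class draws from its own child
of the master seed sequence.

The standard study layout (`default_study_spec`) is a 44×96×72-voxel
volume (308 × 480 × 360 µm) with SN envelopes left and right of the
midline and the VTA straddling it in the caudal half, the A11–13 envelope
rostral to them, and the fascicle tract running ventrally past A11–13
along the full rostro-caudal extent. Control-condition abundances are 32
somata per SN side, 40 in VTA, 42 in A11–13 and 12 fascicles; the
recovery layout (`recovery_study_spec`) enlarges the envelopes so that up
to 60 somata per nucleus remain placeable when vessel corridors cut
through. Intensity levels, blur and noise are free parameters of the
phantom (no published values exist for them); they were fixed once at the
values above as a plausible light-sheet regime.

## Segmentation

`subtract_background` is a clamped high-pass: `max(I − G_σ(I), 0)` with σ
in µm (default 80 µm, i.e., clearly above the nucleus scale so that the
estimate tracks tissue-scale autofluorescence, not the nuclei themselves;
σ = 0 is the identity). `segment` thresholds (absolute value, or a
percentile of the nonzero voxels; an all-zero volume yields an empty mask,
not an error), labels at configurable connectivity (default 26), filters
components by voxel count (default minimum: the voxel volume of a 7 µm
sphere at the volume's spacing), and records per-component descriptors in
µm: volume, mean/max intensity, centroid, and principal-axis extents. The
principal directions come from the second-moment tensor of the voxel
centers; the extent along each direction is the projection range plus the
voxel footprint along that direction, so single-voxel components have
finite extents and elongation (longest/shortest) is always defined.

`exclude_vessels` removes components that are simultaneously long
(longest extent strictly greater than `max_extent_um`, default 100 µm) and
strongly elongated (elongation strictly greater than `max_elongation`,
default 5) — components exactly at a threshold are kept. Survivors keep
their descriptors; only label ids are renumbered.

The full pipeline (`thmorph.stats.measure_phantom`) additionally applies a
two-stage vessel purge before counting: vessel-shaped components are first
detected at a raised threshold (default 60, where blur halos are too small
to bridge a vessel to nearby somata), then deleted from the intensity
volume with an 8 µm dilation margin, and only then is the counting mask
segmented at the working threshold. Without this, rare noise voxels in the
vessel–soma gap can chain somata onto a vessel component at the lower
threshold, and component-level exclusion would discard them together.
Fascicles are themselves tubular, so the slab measurement runs on the
un-purged mask.

## Measuring-sphere counting

The count statistic for a reference cuboid is the number of
fixed-diameter spheres a greedy packing places into the mask:

1. Candidate centers are the mask voxels inside the cuboid, visited in
   order of descending underlying intensity, ties broken by lowest
   `(z, y, x)` index.
2. A candidate sphere is accepted iff at least `fit_fraction` of its
   voxels lie on still-uncovered mask *and* its center is at least one
   diameter (in µm) from every accepted center.
3. Accepting a sphere covers its mask voxels; a rejected candidate center
   is never revisited. The loop ends when no candidate remains.

The fit denominator counts the sphere voxels that exist in the imaged
volume: voxels outside the cuboid but inside the volume count against the
fit (which suppresses spurious spheres on structures only partially inside
a counting region), while voxels beyond the physical volume do not (a
sphere at the specimen border is judged on what was imaged). The procedure
is deterministic, reflection- and rotation-invariant for tie-free
intensity fields, and bounded above by
`mask_voxels / (fit_fraction × sphere_voxels)`.

Defaults: sphere Ø 12 µm (the scale of a developing dopaminergic soma) and
`fit_fraction` 0.5. The study configuration uses `fit_fraction` 0.4: with
only five voxels per ball, a dim soma whose center falls between z-planes
can leave just two thresholded voxels under the ball, and demanding 3/5
systematically misses that subpopulation, while 2/5 admits it without
double-counting (the one-diameter separation rule prevents a second sphere
on the same soma). Left/right cuboid pairs must not overlap (they would
share spheres — a configuration error), and bilateral cuboids must
straddle the configured midline plane (default: the volume center on the
x-axis).

## Pathway units

The tract statistic is measured in a slab placed at the rostral limit of
the segmented (and vessel-purged) A11–13 mask — the most-rostral mask
voxel center along the rostro-caudal axis — extending `thickness_um`
*rostrally* from that limit, so it can never overlap the cell group it is
anchored to, and spanning the full volume cross-section laterally unless
restricted (enlarging the lateral extent beyond the tract adds no units).
The thickness may not exceed the measuring-sphere diameter; equality is
allowed.

Windows are the 26-connected components of the admitted mask clipped to
the slab. Admission is per voxel: a mask voxel joins a window only if its
intensity reaches `min_fascicle_intensity` (study default 110, between the
blurred fiber/halo and fascicle-core regimes), which strips the dim blur
halo — otherwise halos merge adjacent windows and widen them
artificially. Windows whose in-plane footprint is smaller than
`min_fascicle_diameter_um` (study default 8 µm) are dropped; the footprint
size is measured as the *area-equivalent disc diameter* of the window's
projection orthogonal to the rostro-caudal axis. (A maximal inscribed-disc
measure was considered and rejected: at 5 µm in-plane sampling it aliases
by a full voxel, failing legitimate 10 µm fascicles and passing 4 µm fiber
fragments; the area-based diameter separates the two regimes robustly.)

Each window is then packed with measuring spheres under the same greedy
rule, with the fit fraction evaluated over the sphere clipped to the slab
— the slab is thinner than the sphere by construction, so an unclipped
denominator could never be met and every window would degenerate to one
unit, contradicting the intent that massive bundles spawn several spheres.
A nonempty window whose packing accepts no sphere still contributes
exactly one unit (floor rule): a thin fascicle is one pathway unit. For
phantoms of disjoint fascicles no wider than the sphere, units equal the
fascicle count exactly; the statistic is an abundance index of fascicles,
never a neurite count.

The defasciculation summary reports the tract width as the 5th–95th
percentile range of window centroids along the mediolateral axis and the
bundled fraction as the share of admitted voxels in the slab belonging to
retained windows (undefined, and flagged as such, when the slab is empty).

## Group statistics

Group effects are reported as the signed percent change of the treated
mean on the control scale, `100 × (T̄ − C̄)/C̄`, with the standard error of
each arm from the per-animal values.

Significance comes from a two-sided permutation test of
`|mean(treated) − mean(control)|` with relabeling restricted to
preparation-day batches. This stratification absorbs day-to-day staining
and imaging offsets the way a day random effect would in a linear model,
while making no distributional assumptions and remaining exactly
enumerable at small n; classical mixed-model machinery is deliberately not
reimplemented here. When the admissible assignment count is at most
20,000 the test enumerates exhaustively (exact p, including the observed
assignment, so p ≥ 1/N and p = 1 for constant data); otherwise it draws
10,000 Monte Carlo relabelings with the add-one correction
`p = (1 + hits)/(1 + n_permutations)`. Batches containing a single group
are pooled into one common stratum with a warning. Validity under the
null is checked empirically: across 200 simulated null datasets (Poisson
counts with log-normal day effects, 3 batches of 2+2, n = 6 per arm) the
rejection fraction at α = 0.05 is ≈ 0.03, within the nominal-validity
band expected for a discrete exact test.

## The simulated replication study

`run_replication_study` builds control and treated phantom cohorts whose
structure abundances are scaled by injected treated/control ratios
(fascicles 0.267, SN 1.831, VTA 0.570, A11–13 0.617 for the standard
effect structure; abundances round to integers), assigns animals to
preparation-day batches (default 2 per arm per day, so n = 6/6 gives
6³ = 216 admissible stratified relabelings and a minimum two-sided p of
2/216 ≈ 0.0093), measures every phantom with the full pipeline
(`PipelineConfig`: background σ 80 µm, threshold 40, vessel purge at 60
with 8 µm margin, exclusion at 100 µm / 5, sphere Ø 12 µm at fit 0.4, slab
12 µm with admission Ø 8 µm / intensity 110), and compares the groups per
endpoint. The SN endpoint is the left + right sum (per-side counts remain
in the report). Everything derives from the master seed; the study is
fully deterministic.

## What the phantom validation shows — and what it does not

Passing tests establish that the measurement chain is internally correct:
counts recover known ground truth within ±5% under blur, noise, touching
somata and vessel artifacts; pathway units equal the generated fascicle
count exactly in the disjoint regime; injected group effects are recovered
within a few percentage points with valid error rates; and every stage is
deterministic. The phantoms do not emulate scattering, vignetting, stripe
artifacts, staining-penetration gradients, anatomical deformation, or
segmentation ambiguity at real tissue boundaries — so these results bound
algorithmic error, not total error on real specimens, where threshold and
admission parameters must be set against the specimen's intensity regime
(the package defaults mirror the phantom regime, and every such parameter
is configuration-exposed).

## Numerical and degenerate-case notes

- Tube rasterization sets every voxel whose center lies within one radius
  of the centerline polyline; a zero-length centerline paints a ball. A
  tube is guaranteed alias-free only when its radius exceeds the largest
  half-diagonal of the in-plane voxel cell (4.3 µm at (7, 5) µm spacing);
  the public API rejects diameters at or below the largest spacing.
- Cropping uses half-open voxel-center membership and records the physical
  offset, so nested crops compose exactly and coordinates map back to the
  parent frame.
- 16-bit unsigned TIFF is the canonical on-disk form (bit-exact round
  trip); float32 grids are written as float pages for intermediate
  results. The JSON sidecar carries spacing, axis mapping, midline, origin
  and provenance.
- All tie-breaks (packing candidate order, component label order, window
  order) are lexicographic in `(z, y, x)`, making every stage bit-stable
  across runs and platforms.
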