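# Methods

This note documents the models, conventions and design choices behind
`smtract`, in the order data flows through the package.

## Coordinate and field conventions

World space is RAS+ millimetres; voxel indices are 0-based and the affine
maps voxel *centres* to world coordinates. All slab and gate intervals
are half-open `[lo, hi)`, which makes box-intersection tests unambiguous.
Diffusion tensors are stored as 6 lower-triangular components
(xx, xy, xz, yy, yz, zz) in mm²/s; interpolation is trilinear on the
*components*, followed by eigendecomposition — eigenvalue fields are
non-smooth at fibre crossings, so interpolating eigenvalues directly
would be wrong. Eigenvalues are sorted descending and eigenvector signs
are fixed by making the first non-zero component non-negative, so outputs
are bit-reproducible.

FODs use a real, even-order (antipodally symmetric), orthonormal
spherical-harmonic basis with coefficients ordered (l, m), l = 0, 2, …,
m = −l…l. The basis/ordering identifier (`real-sym-em-v1`) is written
into every sidecar file and checked on read; a mismatched identifier is a
hard error rather than a silent mis-read, because basis mismatch is the
classic silent failure of SH pipelines. Default maximum order is 8
(45 coefficients).

## Tracking

Propagation is fixed-step Euler. From a seed, the global FOD maximum
(coarse scan over a 724-direction antipodally symmetric Fibonacci sample,
then hill-climbing refinement with a tangent-plane quadratic fit) gives
the initial direction; the track is extended in both directions, the
second pass starting from the antipode, and the two half-tracks are
concatenated with the seed de-duplicated. At each step the next direction
is the FOD local maximum (same coarse-scan + refinement machinery)
minimizing the angle to the incoming direction, sign-aligned for
continuity. On tensor fields the principal eigenvector plays the role of
the single peak, with the amplitude threshold disabled (an FA floor is
available instead) since an FOD amplitude has no tensor analogue.

A step *completes* only if the new point is inside the grid and tracking
mask and has an admissible peak: amplitude ≥ the FOD threshold and turn ≤
the angle threshold. Otherwise the side ends at the previous point —
there are no partial steps, so lengths are quantized to the step size. A
finished streamline is rejected if shorter than the minimum length. The
maximum length is enforced on the combined two-sided length (first side
gets the full budget, the second the remainder); at the ~30 mm scale of
this tract the 500 mm ceiling never binds.

Parameters (defaults): FOD amplitude floor 0.1 (the phantom normalizes
single-fibre peak amplitude to 1.0 precisely so this threshold has
scale); length window 10–500 mm; presets *low-fidelity* (step 1.0 mm,
angle 45°) for scouting and gate placement and *high-fidelity* (step
0.5 mm, angle 89°) for the final pass. For a 0.5 mm step on the 9.6 mm
arc the per-step turn is 2·asin(0.25/9.6) ≈ 3°, far inside both
thresholds; the angle threshold is interpreted per-step (not per-mm).

Whole-brain seeding places one uniformly random seed inside every mask
voxel. The jitter for voxel *v* comes from a counter-based Philox stream
keyed by (root seed, flattened index of *v*), so a voxel's seed never
depends on which other voxels are masked — adding or removing structures
elsewhere in the volume leaves the remaining streamlines bit-identical.

## Gate protocol

Three gates derive from three anatomical fixed points (anterior
commissure apex, pineal apex, mid-thalamus / inter-thalamic adhesion
centre), supplied as a JSON file in world mm:

* anterior OR gate — axial slab one voxel thick at the AC slice;
  rectangle from 1 mm anterior of the AC extending 10 mm posteriorly,
  ±8 mm laterally;
* posterior OR gate — axial slab one voxel thick at the slice *above*
  the pineal apex; rectangle from mid-thalamus level back to 4 mm behind
  the pineal apex (the apex-to-mid-pineal overshoot), ±6 mm laterally;
* mid AND gate — coronal slab one voxel thick at mid-thalamus; rectangle
  ±10 mm laterally, from 4 mm below to 10 mm above the landmark.

All rectangle extents are configuration (`GateExtents`), since the
underlying protocol describes them qualitatively; the landmark-derived
*positions* are fixed. Selection retains streamlines crossing ≥ 1 OR
gate, every AND gate and no NOT gate, with set semantics. Gate
membership is an exact segment/axis-aligned-box intersection (slab
clipping): the slab∩rectangle region *is* an axis-aligned box, and the
exact test equals dense-resampling membership in the limit while never
missing corner-grazing segments.

Manual cleanup is replaced by declarative NOT templates built from the
same landmarks: a whole-plane coronal pair with margins anterior (2 mm)
and posterior (4 mm — clearing the posterior gate's overshoot) of the
tract's A–P span, and an axial pair 3 mm below the AC slice with
bilateral lateral rectangles (2–12 mm off the midline) for descending
crus-like fibres. A NOT gate overlapping an OR/AND gate box is rejected
at construction.

Splitting clips each retained streamline to the maximal sub-polyline from
its first crossing of the anterior gate's slab mid-plane to its last
crossing of the posterior gate's mid-plane, crossings restricted to the
gate rectangles; polylines are re-oriented anterior→posterior first, and
crossing points are interpolated with the plane coordinate set exactly,
so endpoints lie on the planes to machine precision. Streamlines crossing
either plane more than 4 times are kept but flagged as loop suspects;
streamlines missing either plane are dropped and counted. After
splitting, both boundary gates have effectively been required (AND
semantics), although selection places them as OR gates; both counts are
logged. Left and right SM are not separated — the output is a single
bilateral tract.

The end-to-end `sm_pipeline` mirrors the two-pass workflow: scout
tracking → gate selection + NOT cleanup (counts logged, scout tractogram
discarded) → high-fidelity tracking with the saved gates → splitting →
metrics.

## Metrics

Length is the Euclidean polyline length; tract volume counts unique
voxels visited by streamline points (pass-through, computed on the final
clipped tract) times the voxel volume. Scalar metrics come from the
sorted eigenvalues: MD, AD = λ₁, RD = (λ₂+λ₃)/2, FA, and Westin shape
measures in the λ1-normalized convention C_L = (λ₁−λ₂)/λ₁,
C_P = (λ₂−λ₃)/λ₁, C_S = λ₃/λ₁, which sum to one pointwise; the
trace-normalized variant is behind a flag. Tract means are point-weighted
by default (every streamline vertex); voxel weighting (one sample per
visited voxel centre) is available. Pointwise identities
C_L+C_P+C_S = 1 and MD = (AD+2·RD)/3 hold exactly by construction and
are asserted in tests.

## Reliability and group statistics

The ICC variant is two-way random effects, absolute agreement, single
measures — the standard choice when raters are meant to be
interchangeable — computed from the two-way ANOVA mean squares, with the
McGraw–Wong F-based 95% interval (Satterthwaite df for the agreement
variant); the consistency variant is available by flag. Reliability is
computed on the raw subjects × raters table; rater measures are averaged
before any group statistics.

The gender comparison fits metric ~ intercept + gender + age + eTIV by
OLS (statsmodels); the gender p-value is the partial t-test. Estimated
marginal means evaluate the fit at the sample covariate means; the grand
EMM is the unweighted mean of the two gender EMMs, and intervals use t
with n − 4 residual df — with n = 50 this arithmetic reproduces published
EMM/SE/CI triples of this model family exactly. Partial correlation
residualizes metric and age on the controls (with intercept) and takes
the Pearson r of the residuals, p from t = r·√((n−2−k)/(1−r²)).

## The phantom: what it emulates, and what it does not

Geometry defaults are the study conditions: 64³ grid of 1 mm isotropic
voxels; a semicircular mid-sagittal tube of radius 9.6 mm (arc length
πR ≈ 30.16 mm, matching the ~30 mm tract; chord 19.2 mm separating the
anterior/posterior landmarks), tube diameter 2.0 mm (inside the 1.5–2.5 mm
cadaveric range); tube eigenvalues (1.41, 0.98, 0.98)·10⁻³ mm²/s taken
from the reported tract AD/RD, giving interior FA 0.2175; isotropic
background MD 3.0·10⁻³ mm²/s, a free-water-like value chosen because the
real tract is CSF-bathed. The arc's plane and end planes pass through
voxel centres so that fully interior voxels carry the exact tube tensor.
The tube is truncated flush at its angular ends — it models a tract
*segment*, and rounded end-caps would let tracks coast ~1 mm past the
anatomy the landmarks define.

Voxels whose centre lies within half a voxel of the tube surface get a
volume-weighted mix of tube and background tensors (and FOD amplitude
scaled by the tube fraction), reproducing the partial-volume FA collapse
seen for thin CSF-surrounded tracts. FODs are built per voxel as a
single-fibre axially symmetric kernel exp(−κ(1−t²)), κ = 15, projected
onto order-8 harmonics via its Legendre coefficients and rotated to the
local tangent, peak amplitude normalized to 1.0; the background is
isotropic with amplitude 0.05, deliberately below the 0.1 tracking floor
so the amplitude criterion (not the mask) terminates tracks at the tube
surface.

Distractors emulate the structures a real dissection must exclude: a
fornix-body-like concentric arc 3.5 mm dorsal to the tract spanning
−25°…205° (it crosses the AND gate and pokes past the coronal NOT
margins), and two crus-like oblique tubes 4.5 mm lateral to the midline
that cross the posterior OR and AND gates. The geometry is arranged so
the plain OR/AND protocol would retain distractor streamlines — the NOT
templates are load-bearing, not decorative. A distractor overlapping more
than 20% of the tract tube is rejected as ill-posed. The crus tubes sit
at half-integer lateral offsets: a 1 mm-radius tube centred exactly on a
voxel plane digitizes to a degenerate single-column mask.

The rater-table simulator draws each metric as subject effect + rater
noise with σ²ₛ/(σ²ₛ+σ²ₑ) equal to the target ICC and total SD 10% of the
metric mean; covariates use the cohort's age distribution (mean 29.58,
SD 13.03 years, untruncated Gaussian so population correlation structure
stays exact), balanced gender, and eTIV ~ N(1.45·10⁶, 1.2·10⁵) mm³ with a
+5·10⁴ male offset. A second generator produces per-subject tables with
an *exact* population partial correlation between metric and age given
(gender, eTIV), used for estimator-recovery studies.

What the phantom does **not** emulate: raw DWI signal, gradient tables,
Rician noise, crossing-fibre voxels, susceptibility distortion, or
anatomical variability of the landmarks. Passing tests on the phantom
demonstrates that the geometry, gate logic, metric arithmetic and
estimators behave correctly under known ground truth — not that the
protocol will segment any particular in-vivo dataset.

## Numerical choices

* Peak extraction: 724-direction antipodally symmetric Fibonacci sample;
  local maxima against 6 nearest neighbours; refinement by ≤ 2
  tangent-plane quadratic steps capped at twice the sample spacing. Ties
  break toward larger amplitude via `argmax` determinism.
* The SH kernel order/sharpness pair (8, κ = 15) keeps truncation
  side-lobes below ~0.04 — under half the 0.1 tracking floor.
* Seed jitter: Philox counter streams per voxel index (see Tracking).
* Degenerate inputs: all-zero eigenvalue triples, empty tractograms,
  empty masks, constant residuals and rank-deficient ANCOVA designs all
  raise with specific messages; an empty dissection result is returned
  with a warning flag, not raised.
* Interpolated eigenvalues are clipped at zero before metric evaluation
  (mixing can produce −1e-20-scale noise).

## Problem sizes

The shipped tests and the acceptance script run the pipeline on the
default 64³ phantom (≈ 900 seed voxels, ≈ 550 whole-brain streamlines per
pass) and the Monte-Carlo studies at 2000 replicates (ICC and partial-r
recovery, n = 50 subjects, 2 raters) and 1000 replicates (ANCOVA type-I
rate) — sizes at which estimator means are determined to ≈ ±0.001 and
rates to ≈ ±0.7%, comfortably inside the asserted bands.

## Known limitations

* Deterministic tracking only; no probabilistic or
  anatomically-constrained variants.
* The angle threshold is per-step; with the two preset step sizes the
  same nominal angle implies different curvature limits per mm.
* Tract volume is point-visited voxel counting; extremely sparse bundles
  under-count relative to a segment-rasterizing definition.
* ICC confidence intervals use the standard F approximations, which are
  approximate for the agreement variant at small n.
* The phantom's semicircle is a stand-in for the real tract's
  qualitative "arch"; no quantitative in-vivo curvature is published to
  match against.
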