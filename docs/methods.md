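# Methods

This note documents the models, conventions and defaults behind
`sntarget`, what the synthetic data do and do not emulate, and the design
choices made where the problem left room.

## Coordinate frame and geometry

All coordinates are millimetres, RAS (x right+, y anterior+, z dorsal+).
The stereotactic frame derives from three landmarks: AC, PC and a midline
vertex point. The midsagittal plane contains all three; the AC–PC plane
contains the AC–PC line and the left–right axis; axial planes are
constant-z in the frame basis (ey along PC→AC, ex the midsagittal normal
oriented rightward, ez = ex × ey). Geometry functions assume the atlas
grid has one voxel axis aligned with frame z (asserted to ~0.5°), so
axial slices coincide with voxel slabs.

The trajectory norm uses only the ventralmost and dorsalmost contacts —
deliberately not a regression over all contacts, matching how
reconstructed leads are summarized in practice; lead validity separately
requires all contacts to be collinear within 0.1 mm.

Angles are reported as the acute line-to-plane angle, 90° minus the
line-to-normal angle, folded into [0°, 90°] and unsigned. Typical
implantation angles (≈ 22° to the midsagittal plane, ≈ 50° to the AC-PC
plane) are only meaningful under this convention; the line-to-normal
angle would place them near 68°/40°.

**Max-RN plane.** Per hemisphere, the axial slice maximizing the
ipsilateral red-nucleus voxel count; ties break toward the more ventral
slice so the reference never drifts dorsally on symmetric input.

**Bejjani origin.** Bejjani's line is operationalized as the in-slice
line parallel to the midsagittal plane through the anterior-most
ipsilateral RN voxel center, evaluated in the max-RN slice; the medial
STN border is the most medial STN voxel center within a ±0.5 mm y-band
around the line. A wider band would blur the border on coarse grids; a
narrower one can miss the STN entirely at 0.5 mm resolution. Whether the
line should instead be drawn at a fixed depth below AC–PC is genuinely
ambiguous in the clinical literature; the max-RN slice is used because
the (X, Y) targeting features are defined in that plane.

**Depth** is signed arc length along the trajectory from its max-RN-plane
crossing, ventral-positive — always ≥ the plain z-offset, with equality
only for trajectories perpendicular to the plane.

Left-hemisphere leads are pooled with right ones by reflecting the X
feature so lateral is positive everywhere; Y is unchanged.

## Engagement scoring

Overlap volumes are estimated by voxel-center inclusion at native atlas
resolution (default 0.25 mm isotropic): the number of region voxels whose
center lies inside the sphere times the voxel volume. The estimator is
deterministic and converges to the analytic volume as the voxel size
shrinks; at 0.25 mm a 2 mm sphere is recovered within ~2 % even in the
worst (grid-aligned) case. Tests retain a supersampled/analytic oracle;
the production path never supersamples.

* Contact rule: 1 mm-radius sphere, any overlap ⇒ engagement. A contact
  overlapping both SN compartments takes the larger overlap; an exact
  nonzero tie is assigned to SNr **with a warning** — ties are
  measure-zero at fine resolution but the estimator must be
  deterministic, and the warning keeps them auditable.
* Trajectory rule: union over scenario-eligible contacts. Scenarios
  (`implanted_only`, `plus2mm`, `plus4mm`, `plus6mm`) admit virtual
  contacts up to the stated extension, so engagement is non-decreasing
  along that order by construction.
* VAT: 1 mA volumes of activated tissue are fixed 2 mm-radius spheres;
  percent overlap is relative to the full analytic sphere volume and
  clipped to [0, 100]. No amplitude–radius curve is modeled.
* Depth profiles: half-open 2 mm bins [c−1, c+1) at even centers; empty
  bins are absent, not zero; single-contact bins report SEM 0.
* Central target (CT): STN voxels within 0.75 mm of any voxel face
  shared by the motor and associative compartments, minus the most
  ventral 50 % by voxel-center z-rank (median ties retained dorsally, so
  exactly ⌈n/2⌉ voxels survive). Because the CT overlaps the STN
  compartments it is stored as a boolean overlay, not an integer label.
* Binary MC/CT engagement uses the same 1 mm sphere rule as the SN
  compartments; VAT percent is the graded measure for all regions.

## Synthetic anatomy and cohorts

The generator's purpose is testability with known ground truth, not
anatomical realism. It emulates topology only: an ellipsoidal STN
(~220 mm³) about 12 mm lateral and 4 mm ventral to the mid-commissural
point; the SN ventral–posterior–medial to it; the RN (sphere, equator at
z = −3) medial–posterior. The STN is partitioned into a posterodorsal
motor compartment holding exactly `mc_fraction` (default 0.5) of its
voxels by a quantile cut along (0, −1, 1). The SN splits into a
dorsomedial SNc strip and the SNr remainder by an oblique plane (normal
(−1, −1, 1.17), offset 1.4 mm from the SN center, giving an SNc of ~25 %
of SN volume); the normal is tilted so the SNr/SNc boundary runs roughly
parallel to typical trajectories, keeping a lead's contacts on one side
of the boundary rather than crossing it with depth. Disjointness of SNr
and SNc holds by construction; where ellipsoids abut, voxels resolve by
priority RN > STN > SN. The left hemisphere is an exact voxelwise mirror
(the grid is built symmetric in x), and the volume covers all structures
plus a 4 mm margin.

Cohorts mix three generating intents — SNr-aimed, SNc-aimed, off-target
(default 55 / 30 / 15 %) — with per-class Gaussian features. The SNr and
SNc class means, (2.0 mm, 0.45 mm, 22.3°, 50.1°) and (0.97 mm, −0.66 mm,
22.5°, 49.2°), are the reported clinical per-class means for SNr- and
SNc-engaging trajectories; the spreads (≈1.0–1.4 mm, ≈4–6.5°) are those
standard errors scaled back to cohort size. Off-target means
(−1.0 mm, 1.5 mm, 22°, 50°) describe a trajectory crossing medial and
anterior to the reference point, the typical miss direction. Per-class
feature covariances are not reported anywhere, so features default to
independent draws; a correlation matrix is accepted but unparameterized.
Lead models come from an eight-model registry (4 or 6 contact levels,
0.5 or 1.5 mm spacing; `extended` iff > 4 levels or > 0.5 mm spacing) in
equal proportions by default. Implantation depth of the deepest implanted
contact is Normal(4.5, 1.5) mm of arc below the max-RN plane — chosen
once, during generator design, so that implanted-only SN engagement sits
well below saturation, extension produces a large gain, and almost no
trajectory misses the SN at +6 mm, the qualitative regime reported
clinically; the value was then frozen. Draws with degenerate directions
(angles outside (1°, 89°), sin²MS + sin²AC-PC ≥ 1, or contacts leaving
the volume) are rejected, resampled and logged.

What passing tests on this generator do **not** show: robustness to real
segmentation error, non-ellipsoidal nuclei, registration/brain-shift
artifacts, inter-subject variability of landmark geometry, or directional
(segmented) contacts. Class labels record generating intent only; all
ground-truth engagement labels come from the engagement module.

## Classifiers and rules

Each SN compartment gets its own binary Gaussian-process classifier over
the four z-scored features (two independent models, since trajectory-level
SNr and SNc engagement co-occur; a mutually exclusive SNr-vs-SNc variant
would discard the "both" trajectories). The kernel is a constant times an
anisotropic squared-exponential — anisotropy is essential because the
features mix millimetres and degrees — with a Bernoulli observation
model; inference uses the Laplace approximation to the latent posterior
(scikit-learn's GP classifier), and hyperparameters maximize the
approximate marginal likelihood from a seeded initialization with
restarts (default 2; bounds 10⁻¹–10³ on lengthscales). Far from training
data the latent mean reverts to zero and predictions to p = 0.5, which is
exactly the desired "no recommendation" behavior.

Cross-validation is stratified 5-fold with a fixed shuffle seed and
pooled out-of-fold accuracy. Hyperparameters are optimized once on the
full data and held fixed across folds (refitting only the latent
posterior per fold); this makes a 10-seed CV sweep tractable and changes
fold accuracies negligibly, at the cost of a mild optimism in the
hyperparameters. Per-fold re-optimization is available via
`refit_hyperparams_per_fold`. The confident subset is predictions whose
max-class probability reaches 0.95; its accuracy is reported beside the
overall one. A permutation null for CV accuracy permutes the label
vector against the fixed out-of-fold predictions (1000 draws) — the
standard association test, avoiding thousands of GP refits.

Probability maps evaluate a fitted model on a 4-D grid, default
X ∈ [−1, 3] × Y ∈ [−2, 2] mm (step 0.5) and MS ∈ [10°, 35°],
AC-PC ∈ [35°, 65°] (step 1°) — wide enough to cover every trajectory the
cohort generator can produce. Rule extraction per (X, Y) panel returns
all grid cells with p ≥ 0.95 plus conservative threshold bounds: the
largest axis-aligned angle box contained entirely in the region (exhaustive
search; every angle pair satisfying the emitted bounds is admissible).
Bounds at the grid edge are reported as unbounded rather than invented.
Rule precision is the fraction of held-out trajectories with p ≥ 0.95
whose label is positive; when nothing is selected the precision is
reported absent with a zero count rather than fabricated.

The depth rule is a plain logistic regression of SN membership on
arc-length depth, fit effectively unpenalized; perfect separation is
detected (disjoint class depth ranges) and handled with a ridge penalty
of 10⁻⁴, flagged in the output. The 95 % crossing uses the closed form
(ln 19 − intercept)/slope, emitted for two referents: the contact center,
and the contact's lower border (center + 0.75 mm, half a typical 1.5 mm
contact height), since a depth prescription can be read either way.
Only trajectories whose infinite line intersects the SN ("on track",
sampled at 0.1 mm steps) enter the fit, and each contributes its deepest
*implanted* contact's (depth, in-SN) pair — virtual contacts count toward
the inclusion criterion but not the fitted pairs, because a +6 mm virtual
contact frequently exits the far side of the SN and would invert the
depth–membership relationship.

## Numerical choices and degenerate inputs

* Overlap ties: SNr, warned (see above). CT median-z ties: dorsal.
  Max-RN slice ties: ventral.
* Plane/line parallelism (|l·n| < 10⁻¹²): error, never NaN.
* Feature grids and CSV outputs use fixed 6-decimal formatting; JSON
  keys are sorted — pipeline reruns with one configuration are
  byte-identical, and the run manifest records a configuration hash,
  seeds, library versions and per-artifact sha256s.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the pipeline threads one seed through
  cohort sampling, fold shuffling and kernel restarts.

## Problem sizes

Default analyses use a 0.25 mm atlas (~1.1 M voxels), 612-lead cohorts
for engagement and classifier work, 500–1000-lead held-out cohorts for
precision, and a 120-lead, 0.4 mm demonstration configuration
(`configs/demo.toml`) for the end-to-end pipeline; these sizes keep a
full run in the tens of seconds to a few minutes on one CPU while leaving
every statistic comfortably stable.

## Known limitations

* The anatomy is ellipsoidal and rigid; no deformation fields, imaging
  intensities, or registration are simulated, and hemispheres are exact
  mirrors.
* The VAT model is a single fixed-radius sphere (1 mA); graded results
  do not generalize to other amplitudes or field models.
* GP inference is a Laplace approximation; probabilities near 0.5 can
  differ slightly from expectation-propagation or MCMC posteriors,
  though the ≥ 0.95 rule regions are insensitive in practice.
* Directional (segmented) contacts are treated as their level's center;
  steering is out of scope.
* The Bejjani origin is voxel-quantized; at 0.5 mm resolution it can
  shift by up to one voxel, which propagates directly into the X/Y
  features.
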