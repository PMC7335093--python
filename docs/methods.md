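# Methods

## Problem setting

Deep brain stimulation (DBS) outcomes vary with *where* the stimulation
field sits relative to white-matter pathways. Given (a) a tractogram of
streamlines in a common world space, (b) one binary stimulation volume
(e.g. a volume of tissue activated, VTA) per stimulation setting, with its
amplitude, and (c) a clinical improvement score per setting, the pipeline
asks: which streamlines discriminate good from poor responders, and can a
weight map built from one cohort predict outcomes in another?

The pipeline is deliberately mass-univariate and model-light: one
two-sample t statistic per streamline, a per-stimulation weighted sum, a
correlation, and permutation inference. Nothing here is fit by iterative
optimization, so every number is exactly reproducible from the inputs and
a seed.

## The model

**Connectivity.** A streamline is *connected* to a stimulation setting if
the polyline passes through the support of any of its binary volumes.
Membership is decided by mapping points through the inverse voxel-to-world
affine and rounding to the nearest voxel index (voxel-center semantics).
Polylines are resampled so no inter-vertex gap exceeds `max_step`, by
default half the smallest voxel edge across the cohort's masks; the
default is also an upper bound — larger steps are rejected because a
vertex chain could then skip voxels entirely. Multiple volumes of one
setting (bilateral electrodes) are OR-combined: one clinical observation,
one row of evidence. Connectivity is binary by design; no path-length or
field-strength weighting.

**Fiber t-scores.** For each streamline, stimulations split into a
connected and an unconnected group, and the fiber's weight is the
pooled-variance two-sample Student t statistic on their improvements,
oriented connected-minus-unconnected (fibers recruited by good responders
score positive). Welch's statistic is available by flag; pooled is the
default because it is the classical two-sample test and behaves better at
the tiny group sizes involved. Fibers whose smaller group has fewer than
`min_per_group` members (default 2, the smallest size with an estimable
variance) or whose pooled variance is zero are flagged invalid and carry
weight 0 everywhere downstream — they are never dropped, so fiber indexing
is stable and a model fitted on one cohort applies positionally to
another. No per-fiber p-values or multiplicity correction exist on
purpose: with ~10^5–10^6 fibers the t-values are predictive weights, not
hypothesis tests.

**Aggregation and normalization.** A stimulation's raw score is the sum of
weights of all valid connected fibers (positive and negative alike; the
top-fraction selection exists only for display and atlas export). Because
larger stimulation fields mechanically recruit more fibers, the raw sum is
divided by the stimulation amplitude — for multi-electrode settings, the
total amplitude of the record.

**Inference.** The aggregate score is correlated with improvement
(Pearson by default, matching the linear-fit scatterplots such analyses
report; Spearman by flag). The p-value permutes the improvement vector
`n_perm` times (default 1000) and uses the add-one estimator
`p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)` — never zero, resolution
1/(n_perm+1), two-sided by default with one-sided alternatives by flag.
Permuting the outcome (not the geometry) is the exchangeable null:
stimulation volumes and the connectome stay fixed, outcomes are
re-assigned. The low/high subgroup comparison (settings scoring below vs
above a cutoff) uses a classical pooled t-test, reported low-minus-high.

**Cross-prediction.** The fiber model is fitted on the training cohort
only; the test cohort contributes only its incidence, amplitudes and
outcomes at evaluation time. The firewall is structural (the fitting
function never sees test outcomes) and is asserted by a test that mutates
test outcomes and checks the fitted weights are unchanged.

**Literature targets.** A built-in table of eleven published OCD-DBS
stereotactic targets (MNI coordinates, reported average %-Y-BOCS
improvements where available) supports a coarse external check: spheres of
radius `sphere_radius` (default 3 mm) at both mirrored coordinates stand
in for each study's stimulation field, are scored like any stimulation
(amplitude 1, left + right summed via the OR-combined incidence), and the
overlap is correlated with the reported improvements; rows without a
reported improvement stay in the table but leave the correlation. The
sphere is a declared proxy — published studies report a point, not a
field — so the radius is a sensitivity parameter, not a claim. Only the
printed MNI column is used; no AC/PC conversion is attempted.

## The synthetic generator

Patient MRI and outcome data of this kind are not publicly
distributable, so the test bed is simulated with the structure the method
assumes:

* **Planted bundle** — a cubic-spline centerline through waypoints; each
  fiber offset in the local normal plane by Gaussian coefficients (sd
  `radial_sd` per axis) interpolated smoothly between four stations along
  the arc, so fibers wander gently around the centerline.
* **Background** — correlated random walks (momentum `smoothness`) that
  bounce specularly off a bounding box, arc lengths drawn uniformly from
  `length_range`.
* **Cohorts** — stimulation centers drawn from a cohort-specific Gaussian,
  amplitudes uniform on `amplitude_range`, sphere radius a strictly
  increasing function of amplitude, and
  `improvement = effect_beta * overlap + Normal(0, noise_sd)`, where
  *overlap* is the fraction of planted fibers passing within the sphere.
  A ground-truth sidecar records every draw; the improvements are exactly
  recomputable from it.

All randomness descends from one seed through `numpy` seed-sequence
spawning (one child per stimulation), so draws do not shift when the
cohort is enlarged.

### Default conditions and why

| parameter | default | rationale |
|---|---|---|
| field of view | 72 mm cube, 1 mm voxels | covers a deep-brain-sized region at clinical VTA resolution |
| bundle | 55 mm arc, 200 fibers, radial sd 2 mm | a coherent tract several voxels wide |
| background | 2,000 fibers, 20–60 mm | 10:1 distractor-to-signal ratio |
| cohorts | 20 stimulations each | surgical-cohort scale |
| placements | cohort A offset ~7 mm dorsal, cohort B ~8 mm lateral, sd (10, 4, 4) mm | two surgical targets approaching one tract from different angles, partial overlap |
| amplitude | U(2, 4.5) V, radius = 1.5 + amplitude mm | VTA radii of 3.5–6 mm across a clinical amplitude range |
| outcome | beta = 60, sigma = 10 (improvement %-points) | signal-to-noise that lands the in-sample correlation in the 0.6–0.9 range typical of such analyses |

What the generator does **not** emulate: realistic white-matter geometry,
non-spherical stimulation fields, registration error, inter-patient
anatomical variability, and outcome floor/ceiling effects. Passing tests
therefore demonstrate that the statistical machinery recovers a planted
effect under its own assumptions — not that the method is clinically
valid on real data.

## Numerical choices

* Internal frame: world millimetres, RAS, 0-based voxel indices; TRK's
  corner-origin voxel-mm storage is converted on read/write by
  `nibabel.streamlines`.
* Mask binarization is strictly `> 0`; field-strength thresholding is an
  upstream concern.
* Percent improvement is signed and unclamped (worsening is negative
  evidence, not missing data).
* `top_fraction` takes the `ceil(fraction * n)` largest |t| of the
  requested sign; ties at the cut admit the smaller fiber id.
* Zero pooled variance with unequal means would give ±inf; such fibers
  are rejected as invalid with a warning rather than carrying a sentinel.
* Constant improvement vectors invalidate every fiber (warning), and
  zero-variance score or outcome vectors make correlation an error, not a
  NaN.
* Fitted models persist as TSV (17 significant digits) + JSON header and
  reload bit-identically (`float_precision="round_trip"`).
* Reordering stimulations permutes sums in floating point; statistics are
  reproduced to 1e-12, not bit-identically, under such reorderings.

### Connectivity sampling vs. an exact test

Vertex sampling at any finite step can miss a grazing pass whose chord
through a voxel's rounding cell is shorter than the step; at the default
step this affects on the order of 0.1% of fiber/mask pairs in adversarial
random geometry and none of the aggregate conclusions. The oracle
equivalence test therefore compares the implementation against an
independent brute-force reimplementation at a *matched* 0.05 mm sampling
density, where agreement must be (and is) exact on every entry; the
sampling-density sensitivity itself is documented rather than hidden.

## Problem sizes used in the shipped checks

Unit tests run a reduced experiment (50 planted + 300 background fibers,
12 stimulations). The acceptance checks run the full default experiment
(2,200 fibers, 20 stimulations per cohort), 20 cross-prediction
replicates at 1,000 permutations, and a 500-repetition null calibration
at 500 permutations — sizes chosen so the whole battery completes in a
few minutes on one core while keeping the Monte-Carlo intervals tight
enough to be meaningful.

## Known limitations

* Binary connectivity ignores how much of a fiber lies inside the volume.
* The pooled t-test assumes equal group variances; Welch is offered but
  group sizes of 2–5 limit any variance estimate.
* The amplitude division is a first-order size correction; it does not
  model the nonlinear growth of stimulation fields with amplitude.
* The literature-target sphere proxy ignores each study's device geometry
  and stimulation parameters entirely.
* With few stimulations, many fibers share identical connectivity
  patterns and thus identical t-values; inter-fiber correlation makes
  fiber-level uncertainty statements impossible by construction, which is
  why none are offered.
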