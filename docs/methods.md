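# Methods

This note documents the models, the tunable parameters, the synthetic-data
generators and the numerical choices behind `remotefit`, and what the
passing tests do and do not establish about real data.

## 6MWT distance engine

**Model.** The walked distance is the sum of great-circle chord lengths
between consecutive GPS fixes. Geodesy is the haversine formula on a
sphere of radius 6 371 000 m: over a sub-kilometer walking course the
spherical-vs-ellipsoidal discrepancy is millimetric, far below GPS noise,
so ellipsoidal corrections would be false precision.

**Sampling geometry.** Chord summation systematically *underestimates*
path length wherever the walker turns between two fixes (the chord cuts
the corner) and *overestimates* it when fix-to-fix noise differences
inflate chords. Both effects are properties of 5-s GPS sampling itself,
not of this implementation; the back-and-forth protocol on a short course
concentrates the former at turnarounds.

**Outlier rule and correction.** An interval is flagged when its speed
exceeds `vmax_ms` (default 4.0 m/s — above fast healthy walking, below
running artifacts) or exceeds `median_factor` (3.0) times the median
speed of the `outlier_window` (5) nearest intervals not already flagged
by the hard ceiling. A flagged interval's distance is replaced by the
median speed of its nearest unflagged neighbors times its actual
duration — i.e. the walker is assumed to have kept their local pace
through the glitch. All three knobs are exposed in `WalkConfig`. A track
in which every interval is flagged is rejected as unusable rather than
"corrected" into fiction.

**Start gate and windowing.** The gate returns the earliest time at which
reported horizontal accuracy has been strictly below 15 m for a
contiguous 5 s; any sample at or above 15 m (or missing) resets the run.
In the deployed devices this gate runs *before* recording starts (the
start button is disabled until it passes), so a recorded test-window
track is post-gate by construction; `analyze_walk` therefore defaults to
`apply_gate=False` and, when asked to gate, scores the window
[ready, ready + 360 s], discarding earlier fixes and truncating later
ones. Missing fixes are never imputed: a dropout yields one longer
interval whose speed uses the actual duration.

**Reference equations.** Percent-of-predicted uses the Enright–Sherrill
healthy-adult equations (men: 7.57·height_cm − 5.02·age − 1.76·weight_kg
− 309; women: 2.11·height_cm − 2.29·weight_kg − 5.78·age + 667), floored
at zero.

## 30s-STS counter

**Inputs.** Per-frame 2-D keypoints in the COCO-17 vocabulary with
confidences. Pose estimation itself is upstream: any extractor that emits
this layout works, and the counter never sees pixels.

**Posture classification.** Knee angle = interior angle at the knee of
hip–knee–ankle; hip angle = interior angle at the hip of
shoulder–hip–knee; both computed per side and averaged over the sides
whose four joints pass the confidence threshold (0.3), so a pure profile
view still classifies. Standing requires both angles ≥ 160°, sitting both
≤ 110° (sit-stand biomechanics put seated knee flexion near 90° and
upright extension near 175°); anything between is a transition; a frame
with no usable side is UNKNOWN and simply carries no vote.

**State machine.** Per-frame labels are first median-filtered on their
natural ordering (sitting < transition < standing) with a window of about
one debounce interval, which removes single-frame flickers caused by
keypoint noise near an angle threshold without shifting genuine
transitions. A state then *commits* once it persists ≥ 0.2 s. One
repetition is emitted per committed sitting → … → standing pass, credited
at the frame standing is entered; its onset is the moment the sitter left
the chair. Two robustness rules cover low frame rates and short dwells:
the initial condition is read from the first classified frame (the test
protocol starts seated after a countdown, so demanding a debounced
sitting run before the first rise would drop the first repetition), and a
direct sitting→standing commit (transition run too brief to commit) dates
its onset from the last sitting-labelled frame. A pass that sinks back to
sitting without reaching standing is an incorrect repetition
(incomplete extension).

**Arm check.** Arms-crossed-on-chest is proxied geometrically: both
wrists within 0.6 × shoulder breadth of the shoulder midpoint. A
repetition is correct when that check holds on ≥ 80% of its transition
frames. A low-confidence wrist fails the check — the conservative choice
for a correctness criterion.

**Scoring window.** Repetitions whose onset lies within the first 30 s of
the sequence are scored; later frames can only complete a repetition
already begun, so appending footage after the window never changes the
score.

## Measurement-properties pipeline

* **ICC(2,1)** uses the Shrout–Fleiss ANOVA estimator on the
  complete-case subjects × sessions table, with the standard F-bound
  confidence interval (Satterthwaite df for the session/error mixture).
  It agrees with an independent reference implementation to 1e-10 on
  random tables. Variance components are returned so SEM = √MSE.
* **Covariate-adjusted ICC** fits score ~ age + BMI + phone brand with a
  subject random intercept by REML (statsmodels MixedLM) and reports
  σ²_subject / (σ²_subject + σ²_residual). It tolerates unbalanced
  designs; a design with no repeated sessions is rejected as degenerate.
* **CCC confidence interval** uses Lin's z-transform variance in its
  corrected form; for degenerate inputs (|CCC| = 1 or a constant margin)
  the interval collapses to the point estimate.
* **Within-subject CV** is 100·SD/mean per subject, pooled across
  subjects by root-mean-square — the natural pooling for a variance-like
  quantity; subjects contribute only with ≥ 2 sessions.
* **Grading**: correlation bands very low / low / moderate / high / very
  high at 0.2 / 0.4 / 0.7 / 0.9, CCC bands very poor / poor / moderate /
  good at 0.70 / 0.90 / 0.95, on |value|, boundaries assigned to the
  upper band.
* **Sample size** is the Walter–Eliasziw–Donner approximation with k = 2
  by default (one test-retest comparison); `icc_power_simulation`
  cross-checks the design by simulating the one-way ANOVA F-test of
  H₀: ICC ≤ ρ₀ under ICC = ρ₁.

Subgroup analyses (sex, age bands) are the same pipeline applied to a
filtered table; no special machinery exists or is needed.

## Synthetic-data generators

All generators are bit-reproducible given their spec (which contains the
seed) and return ground truth alongside the data.

**GPS walk.** The true path is back-and-forth on a straight course
(default 100 m, 360 s, one fix per 5 s, walking speed 1.5 m/s),
constructed on a flat local tangent plane and converted to WGS84 around a
configurable origin — adequate below 1 km. Position noise is **first-order
Gauss–Markov** (AR(1)/Ornstein–Uhlenbeck) per axis with marginal SD
`noise_sd` and correlation time 180 s: smartphone GPS error is dominated
by slowly drifting atmospheric/ephemeris/filter biases, and white noise
of the same magnitude would roughly double chord-sum distances at 5-s
sampling — a physically wrong model, not a harder test. Glitches displace
a fix perpendicular to the course so the incoming interval implies
`outlier_speed`. The generator does **not** model multipath geometry,
urban canyons, or satellite constellation changes; engine accuracy on
real city recordings is not established by these tests. In fixtures that
isolate the engine's arithmetic the course length is chosen so
turnarounds coincide with fix epochs (e.g. 90 m at 1.5 m/s), removing the
corner-cutting term; with the study's 100 m course that term is present
and partially offsets noise inflation.

**Sit-to-stand.** Knee/hip angles follow a raised-cosine cycle between
sitting (90°) and standing (175°), mapped to a stick figure with fixed
segment lengths (thigh = shank = 90 px, trunk = 130 px, shoulder breadth
80 px) so the angle→keypoint mapping is invertible; per-frame Gaussian
angle noise emulates extractor jitter. A chosen fraction of cycles is
performed with hanging instead of crossed arms. Real pose-estimation
failure modes — occlusion, identity swaps, systematically biased
keypoints — are not emulated; the recovery results bound performance
under well-behaved extraction only.

**Validation study.** Scores follow the one-way variance-components model
score_ij = μ + b_i + e_ij, b ~ N(0, σ²_between), e ~ N(0, σ²_error), so
the true ICC is σ²_between/(σ²_between + σ²_error) and the true SEM is
σ_error. The paired device score adds a constant bias and independent
device noise. Defaults mirror a healthy-adult 6MWT cohort: 53 subjects ×
3 sessions, μ = 704.55 m, σ_between = 69.9 m and σ_error = 37.1 m
(derived from a total SD of 79.13 m at ICC 0.78), device bias 8.96 m and
device SD 43.8 m (from validity limits of agreement of ±85.9 m).
Covariates (age, BMI, phone brand) are generated with zero effect by
default so the adjusted and unadjusted ICC should agree; effects are
dials for studying adjustment behavior. Learning effects across sessions
are deliberately not modeled.

## Problem sizes used in the checks

Parameter-recovery checks use 100 seeded replicates of a 200-subject ×
3-session study (ICC recovery to ±0.02 of 0.671), 100 seeded noisy walks
(5 m noise, 5% glitches, ≥ 90% within 5% of truth), 200 seeded
sit-to-stand sequences spanning 2–20 cycles, ≤ 5° angle noise and
15/30/60 fps (≥ 99% exact count recovery), and 4000-replicate power
simulations. These sizes give Monte-Carlo standard errors an order of
magnitude below the tolerances they check.

## Known limitations

* The outlier speed threshold and correction rule are this package's own
  design (deployed devices do not publish theirs); they are config-exposed
  rather than claimed canonical.
* The posture thresholds (160°/110°), debounce (0.2 s), arm radius
  (0.6 × breadth) and arm-hold fraction (80%) are defaults from sit-stand
  biomechanics ranges, not fitted values.
* 2-D image-plane angles only; a strongly oblique camera changes apparent
  angles and is not corrected for.
* The CV's pooling convention (RMS of per-subject CVs) is one of several
  in use; comparisons across published CVs should check conventions.
* MIC (minimal important change) values are external benchmarks to
  compare an MDC against, not something this package estimates.
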