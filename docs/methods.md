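# Methods

## Model

The package estimates the direction of the ground reaction force (GRF) on a
skater's supporting leg under a single biomechanical assumption: the
reaction force acts perpendicular to the shoe sole. The sole plane is
reconstructed from three marker-derived points — the rear and front ends of
the skate blade plus a joint center — as an orthogonal triad: the blade
axis y_b (rear→front), x_b = unit(y_b × lever) with lever = joint − rear,
and the sole normal z_b = unit(y_b × x_b). The ankle center gives
estimator Est1, the knee center Est2. The estimated force vector is the
force-plate resultant magnitude F_Σ (in body-weight units, BW) times the
local-frame components of z_b.

The literal cross-product order produces a z_b pointing away from the joint,
i.e. into the ground; the implementation flips its sign so z_b·(0,0,1) > 0,
matching the upward reaction convention. x_b is unit-normalized before the
second cross product and z_b re-normalized, so the estimate is a unit
vector by construction and exactly perpendicular to the blade axis.

The local frame is travel-aligned per frame: Y′ is the unit horizontal CM
velocity (computed by central differences of the filtered CM trajectory,
one-sided at the endpoints), Z′ is global up, X′ = Y′ × Z′. Frames with
horizontal CM speed ≤ 0.1 m/s are rejected as undefined; this threshold is
far below skating speeds (~9–10 m/s) and only guards genuinely stationary
input. Left-leg data from the bilaterally symmetric straight motion are
mirrored (X′ negated) before pooling with right-leg data; curve motions are
kept side-specific.

### Error model and the two levers

Isotropic marker noise of standard deviation σ tilts z_b by roughly
σ/‖lever‖ radians. The knee lever (~0.53 m in the default geometry) is
about 2–3× the ankle lever (~0.19 m), so Est2 is systematically more
stable than Est1 — the ordering the estimator comparison and the
Monte-Carlo property tests verify.

### Linear correction

Where the estimate carries a systematic bias of |bias| ≥ 0.08 BW at any
10% checkpoint (inclusive threshold), a per-component recalibration is
fitted by ordinary least squares with the plate value as response and the
estimate as predictor: true = slope·estimate + intercept. The shipped
default model (slopes 0.847/0.596/0.987, intercepts −0.029/−0.025/+0.030
for X′/Y′/Z′) was fitted on left-leg curve skating only; applying it to a
different motion requires an explicit override flag. The corrected vector
no longer has norm F_Σ. Out-of-sample behavior is assessed
leave-one-participant-out: fit on all other participants pooled, apply to
the held-out trials, report pre/post RMSE and a held-out agreement table.

## Preprocessing

* **Filtering** — zero-phase low-pass by a forward–backward 2nd-order
  Butterworth (effective 4th order), even-reflection padding of 12 samples.
  The dual pass squares the magnitude response and cancels phase lag, the
  convention for marker trajectories.
* **Cutoff selection** — residual analysis: for a 1–30 Hz grid (0.5 Hz
  steps) the RMS residual between raw and filtered series is evaluated on
  the central 80% of the record (edge transients excluded); a line fitted
  to the top third of the grid is extrapolated to 0 Hz as the noise floor,
  and the lowest grid frequency whose residual reaches that floor (with a
  2% relative tolerance, since the extrapolation is itself a percent-level
  estimate) is chosen. Per-coordinate cutoffs are clipped to 9.0–15.0 Hz
  for marker data. Degenerate inputs — no decreasing linear tail (R² <
  0.5), non-negative tail slope, a floor at numerical zero, or a tail
  still decaying steeply (last tail residual < 50% of the first, i.e. pure
  passband droop with no noise plateau) — raise a degenerate-signal error;
  a pure-noise series selects the grid minimum, as there is no signal to
  preserve.
* **Synchronization** — force streams sampled at an integer multiple of the
  marker rate are zero-phase low-passed at 0.4× the target Nyquist
  (4th-order sections, forward–backward) and decimated. The anti-alias
  stage can be disabled for band-limited synthetic data where sample-exact
  pass-through is wanted; any filtering perturbs values above the 1e-9
  tolerance used by the exactness checks.
* **Body-weight scaling** — all forces are divided by body weight in
  newtons (mass·9.81 when given as mass), making every reported force
  dimensionless.

Whether force signals should also be Butterworth-filtered like kinematics
is left to the caller (`filter_forces` semantics via the `antialias` and
cutoff options); the default applies only the anti-alias stage. The local
frame uses instantaneous per-frame CM velocity, not a stride average.

## Stride phases and normalization

The supporting-leg period is bounded by four blade events and split with
half-open intervals (a frame exactly at an event belongs to the following
phase, implementing the one-frame-before boundary convention): contact
[analyzed-on, opposite-off), single support [opposite-off, opposite-on),
push-off [opposite-on, analyzed-off). Phases map to fixed 20/60/20 shares
of a 101-point percent grid (0–100% at 1%). Within each phase, values are
resampled by a cubic spline fitted on that phase's valid frames (linear
interpolation when only 2–3 frames are available, since a not-a-knot cubic
needs four knots); phase boundaries act as knots so no information leaks
across support transitions, and the closing boundary frame is included as
a knot so band edges are interpolated rather than extrapolated. Grid
points at exactly 20% and 80% are owned by the single-support band.

A frame is *analyzable* when both analyzed-blade endpoints lie on the
force-plate rectangle (closed set, default 0.6 × 5.4 m) and the opposite
blade contributes no force — airborne, or fully grounded off the plate.
Frames with the analyzed blade straddling a plate edge or with both blades
on the plate are excluded. A grid point is valid only if its phase has ≥ 2
valid frames, its nearest raw frame is unmasked, and a valid frame lies
within 2% of stride of its source time; aggregation across trials tracks
the per-point sample size, which therefore varies along the stride.

## Agreement statistics

Verification runs at 10% checkpoints (5–95%) per component: n, means ± sd,
OLS of true on estimate, ICC(2,1) computed from two-way ANOVA mean squares
(absolute agreement, single measure; banded <0.5 poor, [0.5, 0.75)
moderate, [0.75, 0.9) good, ≥0.9 excellent; agreement declared at ≥ 0.5),
and Bland-Altman bias (mean of estimate−true), precision (sample sd), LoA
= bias ± 1.96·precision, and a t-based 95% CI of the bias whose exclusion
of zero flags a fixed error. A significant Pearson correlation (α = 0.05)
between pairwise means and differences flags a proportional error; its
slope receives a participant-clustered bootstrap CI (2000 resamples,
seeded) because repeated trials within a skater are not independent. Trials
are pooled across participants at each checkpoint by default (an optional
participant-mean aggregation exists); bias CIs treat trials as independent.
No multiple-testing correction is applied across checkpoints or components
— the flags are descriptive, not confirmatory. Zero between-trial variance
makes the ICC ill-defined and is returned as a degenerate result rather
than raised.

## Synthetic stride generator

The simulator provides study-condition defaults: straight or 26-m-radius
curved path, CM speeds 9.79 (straight) / 8.87 m/s (curve), phase durations
0.16/0.60/0.16 s straight, 0.15/0.48/0.14 s curve-right, 0.14/0.56/0.15 s
curve-left, 300 Hz markers and 900 Hz forces, 0.6 × 5.4 m plate. The model
is purely geometric:

* the CM moves at constant speed and height along the path; the blade
  glides on the course plane beneath it with a constant steering (yaw)
  angle of 12° relative to travel — a realistic nonzero value chosen
  because it couples the roll error of the sole normal (the part that
  scales with lever length) into the Y′ component; with the blade exactly
  parallel to travel the two estimators' Y′ errors would be driven solely
  by shared blade-pitch noise and their ordering would be uninformative;
* the shank leans from vertical by a half-sine push profile (peak 30°)
  plus, on the curve, a constant centripetal lean atan(v²/(Rg)); ankle and
  knee lie in the blade–shank plane, so the noiseless sole normal is exact
  by construction and the end-to-end pipeline reproduces truth to machine
  precision at zero noise (on the straight path, where central-difference
  CM velocity is exact; on an arc the chord–tangent angle ≈ v·Δt/2R ≈
  6·10⁻⁴ rad bounds the attainable identity);
* the resultant force is a raised-cosine bump, zero at blade-on/-off with
  a 1.8 BW peak, directed along the sole normal optionally rotated about
  the blade axis by a configurable perturbation — the ground truth the
  estimators are scored against;
* observed markers are the exact ones plus isotropic i.i.d. Gaussian noise
  (default sd 3 mm, a conventional optical-capture figure).

Cohorts draw per-participant multiplicative random effects on speed, lean
amplitude and phase durations (sd 5% of nominal) and a small systematic
direction bias (sd 0.5°), then per-trial seeds, all reproducible from one
seed. For correction studies, `inject_distortion` rebuilds the truth column
of a paired dataset as slope·estimate + intercept + N(0, 0.005 BW), so the
true-on-estimate regression has known coefficients and the recovery check
is unbiased.

The generator emulates geometric and sampling structure (lever lengths,
plate-limited analyzability, phase timing, marker noise), not ankle-joint
mobility, boot-wall force transfer, ice friction, or real force waveforms.
Passing tests therefore demonstrate the correctness of the algorithms and
the noise-geometry error ordering, not field accuracy on real skaters.

## Problem sizes and numerical choices

The test-suite and reproduction script use cohorts of 4 participants × 2
trials per motion for the estimator comparison (≈ 1 000–1 300 pooled
analyzable frames per motion) and 16 × 7 = 112 trials for correction
recovery and leave-one-participant-out validation — sizes at which every
assertion is stable across seeds while the whole suite completes in about
a minute. Unit-norm and orthogonality contracts use 1e-9 absolute
tolerances; exactness identities (zero-noise round trip, BW scaling
inverse) are asserted at machine-precision scale. All file writes are
atomic (temp file + rename) and byte-reproducible given a seed.

## Known limitations

* The correction model is linear and fitted per component independently;
  cross-component coupling (e.g. the boot-wall mechanism that tilts the
  real force away from the sole normal on the curve-left push-off) is only
  representable as a direction perturbation in the simulator.
* The simulator's force waveform is a single smooth bump; double-peaked or
  impact-loaded profiles are not modeled.
* C3D input is not supported; TRC and CSV are the canonical formats.
* The Y′ (propulsive) component is intrinsically the least observable: it
  is small (0–0.1 BW) and most sensitive to frame and steering geometry.
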