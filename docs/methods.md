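# Methods

`stridepower` estimates the per-second peak horizontal power of a runner
from foot-worn inertial sensors, using an instrumented treadmill's force
plate as the reference. This note documents the models, the numerical
choices, what the synthetic data generator does and does not emulate, and
the open design decisions the package had to resolve.

## Reference power from the force plate

The runner is reduced to a point mass. With `Fy` the antero-posterior
ground-reaction force (GRF) in the running direction, `m` body mass and
`theta` the magnitude of the slope angle, the centre-of-mass (CoM)
acceleration along the running direction is

    ay = (Fy - m g sin(theta)) / m        (level and uphill)
    ay = (Fy + m g sin(theta)) / m        (downhill, running direction
                                           reversed so Fy changes sign)

with `g = 9.81 m/s^2` (configurable). The CoM velocity integrates `ay`
by the trapezoidal rule from each stance onset, starting at the belt speed
`v0y`; `Py = vy * Fy` is the horizontal "power" — one directional
component, not total mechanical power. The per-step reference `P` is the
concentric (positive) peak of `Py` for level/uphill running and the
eccentric (negative) peak for downhill running, where braking dominates.
Peak rather than average power is used because the average would require a
reliable split of stance into braking and propulsion, which foot-worn
sensors cannot yet deliver in the field.

Processing: signals are screened with a Hampel identifier (window 11,
3 scaled MADs — the publication-standard outlier rule here is unspecified,
so this stand-in is exposed in the config; on low-amplitude noise it can
flag benign samples, whose re-interpolation is then a near-identity),
flagged samples are linearly interpolated, and both channels are low-pass
filtered with a zero-phase 3rd-order Butterworth at 25 Hz. Stances are
maximal runs of `Fz > 20 N` lasting at least 40 samples at 1 kHz; the
mid-stance is the peak of the region above 300 N (stances never crossing
300 N are discarded; ties resolve to the earliest sample). The treadmill
grade (%) converts to the angle by `theta = arctan(grade/100)`, since a
grade is a tangent.

Per-step peaks are resampled to a 1-Hz grid: steps bucket into whole
seconds by their cycle midpoint, multiple steps per second average
(arithmetic mean — the least-assuming reducer), empty seconds carry the
previous value forward (leading empty seconds take the first available
value). The same grid carries the features, so rows align 1:1.

## IMU processing

Raw 6-axis signals (512 Hz) are low-pass filtered (zero-phase 4th-order
Butterworth, 50 Hz; zero-phase chosen for consistency with the force-plate
filter). Functional calibration maps the sensor frame to a foot frame:
functional +Z is the mean specific-force direction in a 5-s quiet-standing
window (gravity up; motion above 0.1 m/s^2 norm-std aborts calibration);
functional +X (the sagittal pitch axis) is the dominant principal axis of
gyroscope variance during the initial running steps, orthogonalized
against Z; +Y completes the right-handed triad. The pitch-axis sign is
resolved from gait structure: with the correct sign the dominant positive
pitch-rate peaks are the once-per-stride, evenly spaced, broad mid-swing
rotations, whereas the flipped sign yields contact transients — either an
alternating short/long train (contact vs swing time, never equal while
running) or narrow impulsive peaks. Interval regularity decides; near-ties
fall back to peak width.

Gait cycles run mid-swing to mid-swing (pitch-rate maxima above 2 rad/s,
minimum separation 0.4 s); initial contact (IC) is the pitch-rate minimum
in the first half-cycle, terminal contact (TC) the minimum in the second.
These detectors are surrogates for validated event detectors that live in
prior work; the thresholds are config-exposed. Temporal parameters:
`tc = TC - IC`, `strd` = cycle length, `ts = strd - tc`, and the flight
time `tf` is the gap from a foot's TC to the next contact of either foot
(merged left/right streams). With a single foot, the same-foot TC-to-IC
gap contains two flights plus the contralateral contact, so the fallback
is `tf = (gap - tc)/2` under a symmetric-gait assumption — a documented
limitation.

The spring-mass reduction (half-sine vertical force over the contact)
gives

    fzmax = m g (pi/2) (tf/tc + 1)
    dz    = fzmax tc^2 / (m pi^2) - g tc^2 / 8
    kvert = fzmax / dz            [reported in kN/m]

Orientation comes from strapdown quaternion integration of the angular
rate (midpoint rule at 512 Hz), re-anchored at every mid-stance where the
foot is flat and still, so gyroscope drift cannot accumulate across
strides. The foot-strike angle `fsa` is the sagittal pitch of the foot's
long axis at the sample immediately before IC, measured relative to the
preceding mid-stance (foot-flat) anchor — which makes it the angle
relative to the running surface and therefore slope-invariant. Dorsiflexion
is positive. The first cycle of a recording has no preceding anchor and
reports NaN.

Foot velocity integrates the gravity-compensated specific force
(trapezoidal rule) between consecutive anchors, removes a linear drift
profile so velocity is exactly zero at both anchors (exact for any
constant accelerometer bias expressed in the anchor frame), and rotates
the result back to the foot frame. Strides outside the first/last anchor
are dropped.

## Features, balancing, split

Per stride, four families (146 named columns):

* `Xg` (8): tc, tf, ts, strd, kvert, fzmax, dz, fsa.
* `Xs` (132): for foot acceleration, angular velocity and foot velocity,
  each channel x/y/z plus the Euclidean norm: mean, SD, median, IQR, max,
  RMS, kurtosis (non-excess, normal = 3), skewness, and the three
  Yule-Walker AR(3) coefficients. Constant channels take skewness 0 and
  kurtosis 3 rather than dropping the stride. The source publication
  counts 171 features; the stated construction yields 146 under any
  single-footed scheme, so this package documents its own count.
* `Xa` (4): height, age, mass, leg length.
* `Xc` (2): treadmill speed and grade with additive uniform noise
  emulating field estimation error (full-noise halfwidths 0.16 m/s and
  4.86% grade; the 50% level halves them to 0.08 m/s and 2.43% — the
  printed "[-0.8, 0.8]" half-noise speed range is inconsistent with half
  of 0.16 and is implemented as +-0.08; level 0 is exact and makes the
  pipeline deterministic).

Left- and right-foot strides pool onto the shared 1-Hz grid (per-second
averaging across feet keeps one row per second). Condition classes are
(nearest protocol speed in {8, 10, 12, 14} km/h) x (level/uphill/downhill
by grade sign). Under-represented classes are balanced by random
oversampling with exponent interpolation, `n' = round(n (nmax/n)^alpha)`,
alpha = 0.8; oversampling only duplicates rows, applied to the development
set only. The development/test split is by participant (one third of
participants to the test set) so no subject's rows straddle the split.

## Feature selection

Redundancy uses Kendall's tau in its tie-uncorrected form (tau-a,
`2/(N(N-1)) sum sgn sgn`), computed in O(N log N) by un-normalizing
scipy's tau-b with exact tie counts; an O(N^2) enumeration oracle checks
the conversion in the tests. The threshold 0.8 applies to |tau| so
anti-correlated pairs also count as redundant. Relevance is the discrete
mutual information (bits) between each feature and the reference power,
both discretized into 10 equal-frequency bins (rank-stable, so selection
is invariant to monotone transforms). Pairs at or above the threshold are
processed in descending |tau|; the lower-MI member is dropped (ties keep
the lexicographically earlier name); pairs with an already-dropped member
are skipped. Selection runs on the development set only.

## Estimators

Features are z-scored with development-set statistics; constant columns
are flagged and their coefficients fixed at zero.

**Elastic net.** Minimizes
`sum (P - b0 - x'b)^2 + lambda sum[(1-gamma)/2 b^2 + gamma |b|]` with the
intercept unpenalized and gamma = 0.5. The solver is scikit-learn's
coordinate descent (objective mapping `alpha = lambda/(2N)`,
`l1_ratio = gamma`), with exact closed forms at `lambda = 0` (least
squares) and `gamma = 0` (ridge). The penalty grid spans 4 decades below
the smallest all-zero penalty in 100 log-spaced points and is truncated
where the fraction of deviance explained stops improving by 1e-5 per
step — beyond that point smaller penalties only relax shrinkage noise
into the coefficients. The default selection rule is BIC over
ordinary-least-squares refits of the distinct supports along the path
(refits, because shrinkage bias would pollute the likelihood term),
reporting the least-shrunk fit of the BIC-best support; this rule is
selection-consistent, so planted sparse signals are recovered with an
exactly correct support. Cross-validation rules ('min' and the
one-standard-error rule) are provided as options, with optional grouped
folds; the pipeline uses participant-grouped CV (1-SE) because rows
within a participant are strongly dependent and ungrouped folds leak
subject identity into the penalty choice.

**Neural network.** One hidden layer of 10 tan-sigmoid units and a linear
output (`10(k+1)+11` parameters), trained by Levenberg-Marquardt on
sum-of-squares loss: each epoch solves `(J'J + mu I) d = J'r` with the
analytic Jacobian, damping `mu` adapting by factors of 10. Rows split
internally 80/15/5 (NN15) or 60/35/5 (NN35) — development/validation/
hold-out; the validation share drives early stopping (patience 6), and
training returns the best-validation weights (with a warning, not an
error, if the epoch budget ends first). The response is internally
z-scored for conditioning. Weight init is scaled-uniform and seeded;
training is bit-reproducible given the seed.

One model of each kind is trained per slope condition; the per-condition
winner minimizes MAE on the balanced development rows, with ties
preferring the elastic net as the simpler model.

## Evaluation

Reference and predicted per-second series are smoothed per trial with a
10-s window advancing 5 s (one estimate every 5 s; a 60-s trial yields
11). The signed percentage error `eps = (Pt - Pt_hat)/Pt * 100` (samples
with zero reference excluded and counted) is summarized by bias (median),
precision (IQR, linearly interpolated type-7 quantiles), MAE, the squared
Pearson correlation of the smoothed series and — separately labelled,
since the source is ambiguous about which it reports — the squared
Kendall tau. Bland-Altman mean difference and 1.96-SD limits of agreement
and the cumulative |eps| distribution complete the report.

## Synthetic data generator

The generator emulates the measurement protocol: 1-kHz force plate,
512-Hz foot IMUs, speeds 8-14 km/h, grades -20% to +20% (protocol grid:
0, +-5, +-10, +15, +-20), 5 s of quiet standing before each run.

Forces: per stance, `Fz` is a half-sine with the spring-mass peak; `Fy`
is a braking then propulsive sine lobe whose net impulse balances gravity
along the slope at constant belt speed (steep uphill morphs toward pure
propulsion, steep downhill toward pure braking — as in graded running).
The per-step peak power has a closed form evaluated independently of the
pipeline, which the force-plate chain reproduces within 0.5%.

Kinematics: feet rest during stance (the zero-velocity assumption the
drift correction relies on), advance one stride length per cycle along a
quintic profile with a smooth `sin^3` lift, and pitch through
heel-strike, push-off and mid-swing rotation pulses. Each contact event is
a sharp transient (which event detectors lock onto; its extremum sits
within a few ms of the true event even after the 50-Hz filter) followed by
a broader completing rotation, so the configured foot-strike angle is
recoverable to within 2 degrees at the sample before detected IC. Signals
are emitted in a sensor frame rotated by a configurable mounting rotation,
so functional calibration is exercised nontrivially; gravity is tilted by
the slope angle in the simulation frame.

Realism defaults, chosen once: resting MEMS noise 0.05 m/s^2 (accel) and
0.005 rad/s (gyro); stride-to-stride variability 3% (relative SD of
per-step force amplitudes and per-stride pitch-pulse angles, clipped at
+-15%), with the per-step peak power recorded analytically per step.
Cadence (150 + 6 v steps/min) and duty factor (0.45 - 0.04 v, clipped to
[0.22, 0.42]) follow speed. Cohorts draw anthropometrics from the study
population (age 35 +- 11 y, height 174 +- 10 cm, mass 69 +- 12 kg,
truncated at +-2.5 SD; leg length 0.51 x height + noise) and drop intense
trials (fast, steep, uphill) with increasing probability, reproducing the
imbalance that oversampling must correct.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: individual running styles (all participants
share the speed-determined timing and angles, so the models' job is to
generalize over anthropometrics and conditions, not over technique);
soft-tissue and impact artifacts; treadmill-belt dynamics; fatigue and
drift over a session; magnetometer-relevant heading changes; and the
double-support-free assumption is exact rather than approximate. Accuracy
figures from the synthetic study are therefore an upper bound on what the
method would achieve on the cohort data.

## Problem sizes for the shipped study

The packaged end-to-end study uses 12 participants, 16-s trials on the
full protocol grid with default dropout (about 190 trials), zero
condition-feature noise, and all three candidate models per condition with
a 60-epoch cap for the Levenberg-Marquardt trainer. These sizes are the
package's documented defaults for the synthetic experiment; all of them
are parameters of `generate_cohort`/`PipelineConfig` and scale up freely.

## Known limitations

* Event detectors and their thresholds are surrogates for the validated
  detectors in the wearable-gait literature.
* `fsa` is referenced to the foot-flat stance orientation, not to the
  gravity horizontal; on a treadmill these differ by the slope angle.
* The single-foot flight-time fallback assumes symmetric gait.
* The Hampel outlier rule is not idempotent on broadband noise (benign
  flags are re-interpolated with near-identity changes).
* Mutual information uses a plug-in histogram estimate; with 10 bins it
  is biased upward by about `(bins-1)^2/(2N ln 2)` bits, which cancels in
  the within-pair comparisons it is used for.
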