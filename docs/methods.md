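# Methods

This note documents the models, numerical choices and limitations behind
`iarat`, in the spirit of a methods appendix: what the pipeline assumes,
which knobs matter, and what the synthetic cohorts do and do not show.

## Signal model and conventions

A recording is a uniformly sampled (50 Hz) stream of specific force in the
sensor frame (m/s²), angular velocity (deg/s) and a per-sample rotation
matrix R(t) mapping sensor to global coordinates, as delivered by the
sensor's embedded orientation estimator.  Orientation estimation itself is
out of scope: R(t) is taken as given (or simulated).  Conventions fixed by
this package:

* global frame: z vertical, pointing up; "vertical acceleration" is the z
  component after rotation;
* gravity constant g = 9.81 m/s²; gravity-free acceleration is
  a_glob = R·a_sensor − (0,0,g);
* gyro units deg/s internally — every segmentation rule is relative
  (thresholds are fractions of Ω_max), so only internal consistency
  matters;
* the on-disk format is a plain CSV dialect defined here
  (`t,ax,ay,az,gx,gy,gz,r11..r33` plus a JSON sidecar), since the original
  sensor's binary format is proprietary and irrelevant to the method.

## Filtering

Gyro axes are smoothed with a 4th-order Butterworth low-pass at 2.5 Hz
applied forward–backward (zero phase; the magnitude response is squared, so
the −3 dB point of the one-pass design becomes an amplitude ratio of 0.5).
Whether the smoothing belongs on each axis or on the norm is not uniquely
determined by the method description; filtering **per axis before the
norm** was chosen because it preserves the zero-lag property per component.
Edges use reflective padding of 3·order samples — benign because recordings
start and end at rest, and fixed explicitly for bit-reproducibility.  The
accelerometer stream is *not* low-pass filtered before gravity removal; an
optional cutoff (`JerkConfig.accel_cutoff`, default off) exists for the
jerk computation.

## Segmentation

Movement windows are found automatically as runs of Ω above θ·Ω_max, runs
closer than `merge_gap` merged, the n longest runs kept (ties to the
earlier run) and expanded to midpoints between neighbours; a user-supplied
rough tri-partition (`manual_windows`) overrides detection, mirroring the
original semi-automated operator step.  Within each window the phase onset
and offset are the first up- and subsequent down-crossing of θ·Ω_max.

Numerical choices:

* **Sub-sample crossings.** Crossing instants are linearly interpolated
  between the two straddling samples rather than snapped to the grid.  On a
  50 Hz grid the snap alone contributes up to one full sample of error,
  which would dominate the comparison against analytic crossing times; with
  interpolation the residual error is the (real) bias of the 2.5 Hz
  smoothing, below one sample for θ ≥ 0.20.
* **Ω_max scope.** The threshold reference defaults to the task-global
  maximum of the *filtered* Ω (`omega_max_scope="global"`); a per-window
  reference (`"per_portion"`) is available, as the original description is
  ambiguous between the two.
* **merge_gap = 0.05 s.**  The merge gap must stay below the shortest real
  inter-phase dwell: healthy manipulation pauses average 0.14 s, so a gap
  near that value would fuse the reaching and transport lobes on typical
  healthy recordings.  0.05 s still absorbs brief threshold flicker caused
  by sensor noise.
* **Return termination.**  The hand–table contact is the last local maximum
  of vertical gravity-free acceleration with prominence ≥ 0.5 m/s² (the
  method's description of "peak" does not specify a prominence; 0.5 m/s² is
  far above sensor noise and far below the ~3 m/s² contact transient).
  Without a qualifying peak the threshold offset of the return lobe is used
  and a warning logged.
* **Degenerate dwells.**  Subjects who never pause produce zero-length
  manipulation/release phases (onset = offset); these get duration 0 and an
  undefined jerk index, excluded from aggregates.

Failure mode: when a dwell is so short that Ω never dips below the run
threshold between two lobes, automatic detection reports "insufficient
movement lobes".  This is a real limitation of threshold segmentation — the
original procedure's manual partition existed precisely for such cases —
and the pipeline treats it as a per-task error, isolated from the rest of
the cohort.

## Metrics

Duration is offset − onset per phase; the whole-task window spans first
onset to return termination.  The jerk index is

    JI = ln( (mean_t ‖da/dt‖ / mean_t ‖a‖) · D )

on gravity-free global acceleration, with derivatives by central finite
differences (one-sided at window edges).  Two conventions are deliberate:
the **natural logarithm** and **multiplication** by D (both make JI
dimensionless and land healthy whole-task values near 3, where a base-10
log would land near 1.3 and division by D would carry units of s⁻²).

Z-scores use control means and **SD with the n−1 denominator** (normative
statistics from a small control sample).  Subject-level summaries
(Z_Duration, Z_Jerk) average the parameter across items first and z-score
that mean against the distribution of the same mean in controls
(mean-then-z, the literal reading of "z-scores related to the mean item
duration"; z-then-mean is the main alternative and would differ when item
difficulty varies).

## Clinical analyses

The Nine-Hole-Peg-Test conversion rounds the pegs-per-second rate (9/time)
half-up to two decimals before scaling to a minute; subjects unable to
complete the test score 0 pegs/min.  This reproduces every printed
conversion in the embedded cohort except one row (subject S18, printed 5.4
vs computed 4.8), kept as printed and flagged.  Medians of even-sized
samples are the midpoint of the two central order statistics.

Impairment clustering standardizes (ARAT total, 9HPT pegs/min, FTRS
postural+intention sum) across the cohort and applies UPGMA average linkage
on Euclidean distances.  Pegs/min is the only 9HPT representation defined
for "unable" subjects, and the FTRS sum is the headline tremor column —
the source description names only the three scales.  Standardization makes
the result invariant to affine rescaling of any raw feature, and the SD
convention (n vs n−1) rescales all features equally, so it cannot change
the tree.

The statistics battery is rank-based and two-sided throughout.
Mann–Whitney uses exact enumeration of the permutation distribution of U
(valid under ties) when the pooled sample size is ≤ 16 — chosen so the
study's group sizes straddle the crossover and both paths stay exercised —
and the normal approximation with tie and continuity corrections
otherwise.  Kruskal–Wallis and Friedman use the standard tie-corrected
chi-square forms; Spearman p-values are exact by permutation for n ≤ 9,
t-approximate above.  The post-hoc battery after a significant omnibus
test is all pairwise Mann–Whitney (Kruskal–Wallis) or pairwise two-treatment
Friedman tests (Friedman), Holm-adjusted; the source names the Holm
procedure but not the pairwise statistic, so this is a documented choice.

## Synthetic cohorts

The generator emulates the wrist-sensor morphology of completed ARAT items:

* **Angular speed**: two or three minimum-jerk speed lobes
  (Ω ∝ 16τ²(1−τ)², the canonical bell), anchored so their 25%-of-peak
  crossings fall on the planned phase boundaries; the planned boundaries,
  lobe parameters and closed-form crossing times at any threshold are
  emitted as ground truth.
* **Acceleration**: lobe transport accelerations, a low-frequency hold
  wobble (0.3 m/s² at 1.2 Hz) during dwells, an intention-tremor sinusoid
  (3.5–5 Hz) whose gain ramps over the last 30% of transport and stays full
  through manipulation and release, a raised-cosine impact transient
  (3 m/s², 60 ms) at the hand–table contact, gravity, and white sensor
  noise (0.02 m/s², 0.5 deg/s).
* **Durations**: healthy phase-duration means 0.45 / 0.14 / 0.66 / 0.21 /
  0.67 s (reaching / manipulation / transport / release / return), the
  healthy medians of the study this package operationalises; SDs chosen as
  roughly a quarter of the published non-outlier ranges.  Impaired groups
  scale the means — manipulation most strongly, up to 2.74× for the severe
  group, matching the reported median manipulation-duration increase — and
  carry tremor amplitudes 0.3 / 0.8 / 1.5 m/s².  Dwell draws floor at
  0.05 s, the published healthy minimum.
* **Clinical scores** per simulated MS subject are drawn within the
  published score ranges of their severity group, preserving the rank
  structure the validity analysis needs without inventing distributions.

Sensor-frame signals are produced by inverting the same rotation trajectory
stored in the recording, so gravity removal recovers the generator's global
acceleration exactly in the noise-free case — a strong end-to-end check of
the frame conventions.

What the simulations do **not** capture: biomechanically realistic joint
kinematics, finger movements, marker occlusion, orientation-estimator
drift, and corrective sub-movements.  The last point means healthy
whole-task jerk indices come out slightly smoother (median ≈ 2.7) than the
printed healthy range (≈ 2.9–3.4); the magnitude check in the tests
therefore pins the log convention (natural log lands near 3, base-10 near
1.3) rather than the exact printed interval.  Passing simulation tests
demonstrates internal consistency and recoverability, not agreement with
real-cohort numbers, which would require the original recordings.

## Problem sizes in the test suite

Simulation-based checks run at sizes chosen to keep the full suite fast
while preserving statistical meaning: 100 replicate cohorts of 12 + 12
subjects × 2 items for the discrimination power check, 50 cohorts of 18
subjects for the severity-recovery correlation, 60 tasks × 4 thresholds for
the timing-error table, 100 seeds for duration recovery and 50 × 4 tremor
amplitudes for the smoothness monotonicity check.

## Known limitations

* Threshold segmentation needs a visible Ω dip between lobes; very short
  dwells (< ~0.08 s) require manual windows, as in the original
  semi-automated procedure.
* At θ = 0.15 the 2.5 Hz zero-lag smoothing bleeds adjacent lobes across
  the crossing region and displaces boundaries by more than one sample even
  on noise-free signals — consistent with that threshold having shown the
  largest gold-standard errors; θ = 0.25 is the operating point.
* The jerk derivative amplifies high-frequency noise; with very noisy
  accelerometers enable `JerkConfig.accel_cutoff`.
* Clustering and score conversions assume the exact feature set and
  rounding described above; alternative choices (e.g. raw 9HPT seconds as a
  feature) are not interchangeable because "unable" times are undefined.
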