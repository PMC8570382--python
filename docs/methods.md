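# Methods

## The measurement problem

Which body position an infant is in — held by a caregiver, supine,
prone, sitting, or upright — shapes what the infant can see, reach and
practice, and is therefore a developmental variable worth measuring
across whole days rather than short lab visits. Video is the gold
standard but cannot cover a day. posturekit implements the wearable
alternative: a short, video-coded training period at the start of a
session is used to fit a classifier over inertial-sensor features,
which then labels the rest of the (unvideoed) day.

The pipeline is deliberately simple and auditable: interval-coded human
annotations, impulse-based clock alignment, overlapping fixed-length
windows, order-statistics features, and a stock random forest. No stage
contains a learned component other than the forest.

## Pipeline stages and their conventions

### Sensor ingest (`sensor_io`)

Raw per-sensor CSVs are cleaned (rows sorted by timestamp, duplicate
timestamps collapsed to the first occurrence, non-numeric rows dropped
and counted in a QC log) and carried in canonical units: acceleration
in g (1 g = 9.81 m/s²), angular velocity in deg/s, time in float64
seconds relative to file start. Dialects declare column layouts and
unit conversions; split accel/gyro exports are merged on timestamp.
Jittered Bluetooth timestamps can be resampled onto an exactly uniform
grid by linear interpolation. Linear (not nearest-sample)
interpolation is used because small timestamp jitter is smooth; gaps
longer than 0.5 s are never interpolated across — samples inside them
are flagged invalid and any window touching them is later excluded —
because a long dropout bridged by a straight line would fabricate
stillness. Device clock offsets are deliberately not corrected here;
that is the synchronization stage's single responsibility.

### Annotation (`annotation`)

Position annotations are half-open `[onset, offset)` intervals in
seconds, non-overlapping, with gaps meaning "uncoded" (transitions,
garment off, unidentifiable posture). Half-open intervals tile a
timeline exactly, so a grid point at a boundary belongs to the
following interval and no sample is counted twice. Verbose activity
codes (crawling, highchair, held-walking, cruising…) map onto the five
classes through a configurable alias table; anything unrecognized
becomes the `none` sentinel, which is never trainable.

Interrater agreement between two coders is computed per sample on the
label grid (samples where either coder is uncoded are dropped), since
per-sample agreement is the resolution at which labels enter training.
The disagreement mask marks samples where both coders coded but
disagree; by default the resulting window exclusion applies to training
only, keeping evaluation data untouched, with an option to extend it.

### Synchronization (`synchronize`)

Sensors and video share no clock; both record the same mechanical
impulse (sensors struck together in view of the camera). The detector
returns the time of the maximum of |‖accel‖ − 1 g| inside a search
interval; a maximum below the prominence threshold (default 2 g) is an
error that prompts a manual timestamp rather than a silent guess. Each
sensor is aligned by its own peak — the strike is physically
simultaneous — and every clock is translated so the impulse is t = 0.
A closing impulse verifies drift:
`drift = Δt_sensor − Δt_video` between the two events, flagged above
0.5 s. No drift correction is applied by default (none was needed in
the validation data this pipeline reproduces); a linear correction is
available behind a flag for multi-hour sessions.

### Windowing (`windowing`)

The aligned stream is cut into 4-s windows stepped every 1 s, anchored
at the sync event, giving `floor((T − 4)/1) + 1` windows and 200
samples per window at 50 Hz. A window is labeled only when one class
covers ≥ 75% of its samples (the "3 of 4 seconds" rule); `none`
samples never count toward a class. The rule is operationalized on
sample counts, not wall-clock seconds, so it is exact at any rate.
Windows with < 75% single-class coverage, any invalid sensor sample, or
(in the training view) any coder-disagreement sample are excluded with
a machine-readable reason. Windows that straddle an uncoded gap but
still reach 75% coverage of one class are kept — the rule as stated —
though the stricter alternative (drop any gap-touching window) would
also be defensible. Overlapping windows may straddle the train/test
split boundary; an optional purge flag can drop the boundary windows
for stricter leakage control, but the default mirrors the validated
protocol.

### Features (`features`)

Per placement × signal × axis channel, ten summary statistics over the
window: mean, SD, skew, kurtosis, min, median, max, 25th and 75th
percentile, sum. Conventions (recorded in the registry manifest and
folded into its hash): sample SD with n−1; Fisher–Pearson g1 skewness;
excess kurtosis g2; linear-interpolation percentiles. A zero-variance
channel gets skew = kurtosis = 0 rather than NaN, with "zero variance"
judged against rounding-noise scale so an exactly constant channel
stored in float64 still counts. Three sensors × 2 signals × 3 axes ×
10 statistics = 180 base features.

Derived features aggregate the per-channel *window sums*: across the
three sensors within each signal × axis (sum and root-sum-of-squares
"magnitude", 12 features) and across the three axes within each sensor
× signal (again sum and magnitude, 12 features) — 24 derived, 204
total for the 3-sensor profile. The same construction yields 268 for
the 4-sensor home profile (240 base + 28 derived). Pairwise axis/sensor
Pearson correlations and mean-absolute-difference scores are
implemented as optional registry groups, disabled by default: enabling
every pairwise group would far exceed the canonical 24-feature derived
set, so the sum/magnitude groups are the default, documented scheme.

The registry fixes feature order and identity; its hash is stamped into
every trained model, and prediction refuses feature tables built under
a different registry.

### Models (`models`)

scikit-learn's `RandomForestClassifier` with 750 trees and
mtry = floor(√n_features) (so 14 of 204). These are fixed defaults of
the validated pipeline, not tunable knobs of this package; no
hyperparameter search is included. Class imbalance is left unweighted,
matching the stock-forest protocol. Training is seeded and the seed is
stamped into model metadata; a golden-seed regression test pins the
library's behavior rather than re-implementing tree induction.

The individual regime splits each participant's windows
chronologically *within each class* — first round(0.6·n) windows (half-up
rounding; the protocol statement "first 60%" is symmetric about .5) to
training, rest to testing — so every position the infant produced is
represented in training even though the guided activities are
sequential. A class with a single window goes entirely to training
with a warning. The group regime is leave-one-subject-out over full
sessions: the held-out participant contributes no windows (not even
their "training" 60%) to the group model that predicts them.

### Evaluation (`evaluate`)

Overall accuracy is the fraction of windows whose prediction matches
the human code — because windows are equal-length, also the fraction
of time correctly classified. Cohen's kappa
κ = (p_o − p_e)/(1 − p_e) with p_e from marginal products corrects for
base rates; it is undefined (an error, not 0) when both sequences are
a single identical class. Kappa values are binned on the Landis–Koch
scale after decimal half-up rounding to two places (0.805 → 0.81 →
"Almost Perfect"; binary-float rounding would misplace such edge
cases). Per class: prevalence (% of windows), sensitivity = TP/actual
and PPV = TP/predicted, with PPV reported as *missing* rather than 0
when a class was never predicted — means over defined values only, so
an unpredicted rare class does not drag averages. Per-class summaries
over a cohort are conditional by default (averaged over participants
who exhibited the class); an unconditional mode exists.

Prevalence agreement uses Pearson r between actual and predicted class
proportions, per class and pooled over class × unit pairs, where a
unit is a participant or a fixed-length time interval (default 7.5 min)
for within-day tracking. Model types are compared with a two-sided
paired t-test across participants; the bundled-table reanalysis orders
the pair as (group − individual), so negative t means individual
models win, matching the published sign convention. The timeline
report merges consecutive same-label windows into episodes, renders
garment-removal intervals as gaps and totals each class's share of
classified time.

## The simulator: what it emulates, what it does not

`synthetic` generates sessions with the statistical structure the
classifier assumes, so the whole pipeline is testable without any
recordings:

* **Orientation**: each class fixes a unit "up" vector per sensor
  (resting accelerometers read 1 g opposing gravity). Supine and prone
  differ by the sign of the anterior axis; sitting and upright differ
  mainly in thigh/hip pitch; held is a tilted intermediate.
* **Dynamics**: upright carries a 2 Hz gait bounce and intermittent
  ankle/thigh gyro bursts; prone (crawling) carries 1.5 Hz ankle gyro
  bursts (150 deg/s, 50% duty); held carries a 0.8 Hz whole-body sway
  plus a 1.8 Hz caregiver-gait component; sitting and supine are
  near-still with small fidgets and kicks.
* **Nuisance structure**: white noise (defaults 0.05 g accel,
  5 deg/s gyro), a per-participant random rotation of bounded angle
  (default ≤ 10°) emulating garment-placement variability, 2-s uncoded
  transition gaps with tripled motion noise, independent device-clock
  offsets per sensor and for the video, and 8 g sync impulses at the
  scheduled times.

The default schedule is the guided protocol: nine 60-s activities
(standing, walking, crawling, floor sitting, supine, prone, held
stationary, held walking, highchair) followed by 300 s of free play in
random 5–30 s bouts. All randomness flows from one seeded generator;
identical seeds give bit-identical sessions. Cohorts draw
per-participant sub-seeds from a spawned seed sequence, and ability
profiles control class repertoires (the "young" profile omits upright,
as a pre-standing infant would).

What the simulator does **not** emulate: real infant biomechanics
(movement is far richer than sinusoids and square-windowed bursts),
postural ambiguity (a cradled infant can look supine to the sensors),
sensor saturation and temperature drift, or caregiver handling noise.
Consequently the simulated classes are more separable than real ones:
near-perfect simulated accuracies demonstrate that the pipeline is
correctly wired end to end and that its directional properties hold
(individual ≥ group accuracy under placement jitter; prevalence
correlations near 1), **not** that real-world accuracy would be this
high. Real-data performance must come from real recordings; the
bundled published validation table records what this pipeline achieved
there (mean individual accuracy 0.98, kappa 0.95; group 0.93/0.82).

## Problem sizes and numerical choices

* The cohort experiments in the test suite and acceptance script use
  15 participants with full default sessions (~900 s, ≈ 790 labeled
  windows each) for individual models, and run the leave-one-subject-out
  comparison on an 8-participant sub-cohort: a 750-tree group forest
  trains on ~5,500 windows × 204 features, which keeps the full
  experiment to a few minutes on one core while preserving the
  directional individual-vs-group comparison.
* Sync detection tolerates ±1 sample; drift tolerance 0.5 s.
* Resampling is exact on already-uniform input (identity within 1e-9)
  and the aligned CSV round-trips values at 9 significant digits.
* Ties in the window-majority rule cannot produce two qualifying
  classes (two classes cannot both cover ≥ 75%); the unique argmax is
  taken and anything below threshold is excluded.
* Undefined statistics are surfaced, never silently zeroed: kappa with
  p_e = 1, paired t with zero-variance differences, Pearson r with a
  constant margin, agreement with no co-coded samples all raise or
  report missing.

## Known limitations

* The simulator's separability ceiling means simulated accuracy is an
  upper bound sanity check, not a performance claim.
* The 24 canonical derived features are one defensible reading of
  "sums and magnitudes across sensors and axes"; the optional
  correlation/difference groups cover the broader reading but change
  the feature count and are therefore off by default.
* Interrater agreement is defined per sample; window-level agreement
  would differ slightly near boundaries.
* No frequency-domain features, no model calibration, no bootstrap
  confidence intervals — out of scope by design.
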