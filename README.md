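# posturekit

Classify infant body position — **held, supine, prone, sitting,
upright** — from wearable inertial sensors, across a whole day, from a
short video-coded training period.

Infant motor researchers want to know how much time babies spend in
each body position in daily life, because position shapes what infants
can see, reach and practice. Video coding is accurate but cannot cover
a day. posturekit implements the wearable alternative: 3–4 inertial
measurement units (IMUs, each a 3-axis accelerometer + 3-axis
gyroscope at 50–62.5 Hz) are synchronized to a brief video-coded
session, and a classifier trained on that session labels the rest of
the day from motion alone. The package is aimed at developmental and
movement scientists processing such recordings, and ships a synthetic
IMU simulator so the entire pipeline is testable without any data
collection.

## The method

1. **Synchronize.** Sensors and camera record a shared mechanical
   impulse (sensors struck together on camera). The acceleration peak
   — argmax of |‖a‖ − 1 g| — zeroes each sensor clock; the video
   timestamp of the strike zeroes the annotation clock. A closing
   impulse verifies there was no drift.
2. **Window.** The aligned stream is cut into 4-s windows every 1 s
   (200 samples at 50 Hz). A window is labeled with a position only if
   that position covers ≥ 3 of its 4 seconds; transition and
   coder-disagreement windows are excluded.
3. **Featurize.** Per sensor × signal × axis: mean, SD, skew,
   kurtosis, min, median, max, 25th/75th percentile, sum → 180 base
   features for the 3-sensor profile; cross-sensor and cross-axis sums
   and magnitudes of the window sums add 24 more → **204 features**.
4. **Classify.** A random forest (750 trees, mtry = ⌊√204⌋ = 14),
   either *individual* (trained on the chronologically first 60% of
   each participant's windows within each class, tested on the rest)
   or *group* (leave-one-subject-out across participants).
5. **Validate.** Confusion matrix, overall accuracy, Cohen's
   κ = (p_o − p_e)/(1 − p_e) with Landis–Koch bins, per-class
   sensitivity and positive predictive value, prevalence, Pearson r
   between actual and predicted prevalence (per participant or per
   7.5-min interval), and a paired t-test comparing model types.

## Worked example

```python
from posturekit import default_guided_schedule, simulate_session
from posturekit.pipeline import run_individual_pipeline
from posturekit.synthetic import SimulatedParticipant

session = simulate_session(default_guided_schedule(seed=8), seed=8)
result = run_individual_pipeline(SimulatedParticipant("P01", "standard", session))
print(result.report.to_text())
```

prints

```
windows: 317
overall accuracy: 1.00
kappa: 1.00 (Almost Perfect)

position    prev %    sens     ppv
supine        7.57    1.00    1.00
prone        26.50    1.00    1.00
sitting      25.87    1.00    1.00
upright      21.14    1.00    1.00
held         18.93    1.00    1.00
```

The simulated session follows the guided protocol (nine 60-s elicited
activities plus 5 min of free play). 317 held-out windows (the last
40% within each class) were all classified correctly: accuracy is the
fraction of 4-s windows whose predicted position matches the human
code, kappa corrects that for class base rates, and per class the
prevalence (% of test windows), sensitivity (actual windows found) and
PPV (predictions that were right) are shown. Simulated positions are
more separable than real infant data — perfect scores here verify the
pipeline's wiring, not real-world performance (see `docs/methods.md`).

More scripts in `examples/`: session simulation, sync + windowing,
individual-vs-LOSO cohort comparison, and reanalysis of the bundled
published validation table (15 infants: mean individual-model kappa
0.95 vs group-model 0.82, paired t(14) ≈ −3.3).

## Command line

A thin CLI wraps the same stages for file-based work:

```bash
posturekit simulate --n 1 --seed 4 --out data/
posturekit run --config session.yaml          # sync → … → report
posturekit sync --config session.yaml         # or stage by stage
```

Inputs are per-sensor CSVs (built-in "metamotion" and "biostamp"
dialects), Datavyu-style annotation CSVs (onset, offset, code), and an
optional garment-removal log; outputs are the aligned-dataset CSV,
window/feature tables, a serialized model, prediction tables, report
JSON/text and a day timeline. Every JSON artifact embeds a provenance
block (config hash, feature-registry hash, seed).

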