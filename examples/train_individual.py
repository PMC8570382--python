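"""Train and validate an individual body-position model for one session.

Runs the full chain — sync detection, alignment, windowing, the 204
motion features, a within-class 60/40 chronological split, a 750-tree
random forest — and prints the validation report: overall accuracy,
Cohen's kappa with its Landis-Koch bin, and per-class prevalence,
sensitivity and positive predictive value on the held-out 40%.
"""

from posturekit import default_guided_schedule, simulate_session
from posturekit.pipeline import run_individual_pipeline
from posturekit.synthetic import SimulatedParticipant

session = simulate_session(default_guided_schedule(seed=8), seed=8)
participant = SimulatedParticipant("P01", "standard", session)

result = run_individual_pipeline(participant)
print(f"windows: {len(result.features)} labeled "
      f"({len(result.train)} train / {len(result.test)} test)\n")
print(result.report.to_text())
print("\nactual vs predicted prevalence on the testing set (fractions):")
for cls in result.actual_prevalence.index:
    print(f"  {cls:<8} actual {result.actual_prevalence[cls]:.3f}  "
          f"predicted {result.predicted_prevalence[cls]:.3f}")
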