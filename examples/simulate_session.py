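"""Simulate one guided-protocol session and inspect its structure.

Builds the default schedule (nine 60-s elicited activities, five
minutes of free play in random 5-30 s bouts, 2-s uncoded transitions),
renders it into three-sensor IMU streams, and prints how much time each
body-position class occupies — the ground truth later stages try to
recover.
"""

import numpy as np

from posturekit import default_guided_schedule, simulate_session

schedule = default_guided_schedule(seed=0)
session = simulate_session(schedule, seed=0)

print(f"session length: {schedule.total_s:.0f} s "
      f"({len(session.truth_grid)} samples at 50 Hz, "
      f"{len(session.recording.placements)} sensors)")
print(f"sync impulses at t = {schedule.opening_sync_s:.1f} s "
      f"and t = {schedule.closing_sync_s:.1f} s (session clock)")

labels = session.truth_labels
coded = labels[labels != "none"]
print("\nscheduled class shares (percent of coded time):")
for cls in ("supine", "prone", "sitting", "upright", "held"):
    print(f"  {cls:<8} {100 * (coded == cls).mean():5.1f} %")
print(f"uncoded transitions: {100 * (labels == 'none').mean():.1f} % of the session")

hip = session.recording.sensors["right_hip"]
mag = np.linalg.norm(hip.accel, axis=1)
print(f"\nhip accel magnitude: median {np.median(mag):.3f} g "
      f"(resting sensors read 1 g), max {mag.max():.1f} g at the sync strike")
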