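"""Detect sync impulses, align a session, and cut labeled windows.

Each sensor's clock is zeroed at the detected 8 g strike; the
annotation clock is zeroed at the video timestamp of the same strike.
The aligned stream is then cut into 4-s windows every 1 s, labeled by
the 3-of-4-s majority rule.
"""

from posturekit import (
    align_session,
    default_guided_schedule,
    detect_sync_impulse,
    extract_windows,
    simulate_session,
)
from posturekit.evaluate import timeline_report
from posturekit.windowing import window_table

session = simulate_session(default_guided_schedule(seed=4), seed=4)

events = {}
for placement, series in session.recording.sensors.items():
    t0 = series.timestamps[0]
    events[placement] = detect_sync_impulse(series, (t0, t0 + 30.0))
    truth = session.sensor_sync_opening[placement]
    print(f"{placement:<12} impulse detected at {events[placement]:8.2f} s "
          f"(injected at {truth:8.2f} s)")

ds = align_session(
    session.recording,
    events=events,
    video_event_time=session.video_sync_opening,
    track=session.track,
)
windows = extract_windows(ds)
table = window_table(windows)
print(f"\naligned grid: {len(ds)} samples, {len(windows)} windows of "
      f"{windows[0].length} samples each")
print("window label counts (excluded windows span transitions):")
print(table.groupby(["label", "excluded_reason"], dropna=False).size().to_string())
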