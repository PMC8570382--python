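"""Clock alignment between sensors and video via mechanical sync impulses.

Before a session the sensors are struck together (or dropped) in view
of the camera, producing a sharp spike in every accelerometer and a
visible video event.  Detecting the spike gives each sensor's clock a
common zero; the video coder's timestamp of the same moment zeroes the
annotation clock.  A closing impulse at the end of the session verifies
that clocks did not drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import AnnotationTrack, RemovalLog, apply_removal_log, sample_labels
from .errors import AlignmentError, NoImpulseError
from .sensor_io import Recording, SensorTimeseries
from .windowing import AlignedDataset


@dataclass
class SyncEvent:
    """One detected or manually entered synchronization impulse."""

    placement: str
    sensor_time: float
    video_time: float = 0.0
    kind: str = "opening"  # "opening" | "closing"
    detection: str = "auto"  # "auto" | "manual"


def detect_sync_impulse(
    series: SensorTimeseries,
    search_interval: tuple[float, float],
    min_prominence_g: float = 2.0,
) -> float:
    """Time of the strongest acceleration impulse in a search interval.

    The impulse statistic is |(Euclidean accel magnitude) - 1 g|, the
    deviation from rest.  Returns the timestamp of its maximum; if that
    maximum is below ``min_prominence_g`` there is no credible impulse
    and a manual timestamp must be supplied instead.
    """
    lo, hi = search_interval
    t = series.timestamps
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(f"search interval [{lo}, {hi}] outside series span [{t[0]}, {t[-1]}]")
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise NoImpulseError("search interval contains no samples")
    dev = np.abs(np.linalg.norm(series.accel[mask], axis=1) - 1.0)
    peak = int(np.argmax(dev))
    if dev[peak] < min_prominence_g:
        raise NoImpulseError(
            f"{series.placement}: strongest deviation {dev[peak]:.2f} g below "
            f"prominence threshold {min_prominence_g} g; supply a manual sync time"
        )
    return float(t[mask][peak])


def align_session(
    recording: Recording,
    events: dict[str, SyncEvent | float],
    video_event_time: float,
    track: AnnotationTrack | None = None,
    reliability_track: AnnotationTrack | None = None,
    rate: float | None = None,
    removal_log: RemovalLog | None = None,
    max_gap_s: float = 0.5,
) -> AlignedDataset:
    """Shift every clock so the opening sync event is time 0 and resample.

    Each sensor's timestamps are translated by its own impulse time
    (the strike is simultaneous across sensors), then all sensors are
    linearly interpolated onto one shared grid starting at 0 at the
    configured rate.  Annotation tracks are shifted by the video event
    time and sampled per-grid-point into label sequences.
    """
    rate = rate or recording.nominal_rate
    missing = [p for p in recording.placements if p not in events]
    if missing:
        raise AlignmentError(f"no opening sync event for placements: {missing}")
    shifted: dict[str, SensorTimeseries] = {}
    for p, series in recording.sensors.items():
        ev = events[p]
        t0 = ev.sensor_time if isinstance(ev, SyncEvent) else float(ev)
        shifted[p] = series.shifted(-t0)

    t_end = min(s.timestamps[-1] for s in shifted.values())
    if t_end <= 0:
        raise AlignmentError("no common data after the sync event")
    n = int(np.floor(t_end * rate + 1e-9)) + 1
    grid = np.arange(n) / rate

    data: dict[str, np.ndarray] = {}
    valid = np.ones(n, dtype=bool)
    for p, series in shifted.items():
        t = series.timestamps
        chans = series.channels()
        block = np.column_stack([np.interp(grid, t, chans[:, j]) for j in range(6)])
        data[p] = block
        valid &= grid >= t[0]  # no extrapolation before a sensor started
        gaps = np.flatnonzero(np.diff(t) > max_gap_s)
        for i in gaps:
            valid &= ~((grid > t[i]) & (grid < t[i + 1]))

    if track is not None:
        labels = sample_labels(track.shifted(-video_event_time), grid)
    else:
        labels = np.full(n, "none", dtype=object)
    if removal_log is not None:
        labels = apply_removal_log(labels, removal_log.shifted(-video_event_time), grid)
    rel = (
        sample_labels(reliability_track.shifted(-video_event_time), grid)
        if reliability_track is not None
        else None
    )
    return AlignedDataset(
        grid=grid, rate=rate, data=data, valid=valid,
        labels_primary=labels, labels_reliability=rel,
    )


@dataclass
class DriftReport:
    """Per-sensor clock drift between opening and closing sync events."""

    drift_s: dict[str, float | None]
    flagged: dict[str, bool]
    verified: bool
    tolerance_s: float

    @property
    def ok(self) -> bool:
        return self.verified and not any(self.flagged.values())

    def to_dict(self) -> dict:
        return {
            "verified": self.verified,
            "tolerance_s": self.tolerance_s,
            "drift_s": self.drift_s,
            "flagged": self.flagged,
        }


def check_drift(
    opening: dict[str, SyncEvent],
    closing: dict[str, SyncEvent] | None,
    tolerance_s: float = 0.5,
) -> DriftReport:
    """Compare sensor-elapsed vs video-elapsed time between sync events.

    drift = (closing.sensor_time - opening.sensor_time)
          - (closing.video_time - opening.video_time); sensors whose
    |drift| exceeds the tolerance are flagged.  Without a closing event
    the report is marked unverified (no drift values).
    """
    if closing is None or not closing:
        return DriftReport(
            drift_s={p: None for p in opening},
            flagged={p: False for p in opening},
            verified=False,
            tolerance_s=tolerance_s,
        )
    drift: dict[str, float | None] = {}
    flagged: dict[str, bool] = {}
    for p, op in opening.items():
        cl = closing.get(p)
        if cl is None:
            drift[p] = None
            flagged[p] = False
            continue
        d = (cl.sensor_time - op.sensor_time) - (cl.video_time - op.video_time)
        drift[p] = float(d)
        flagged[p] = abs(d) > tolerance_s
    verified = all(v is not None for v in drift.values())
    return DriftReport(drift_s=drift, flagged=flagged, verified=verified, tolerance_s=tolerance_s)
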