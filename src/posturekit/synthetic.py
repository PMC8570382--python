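"""Synthetic multi-sensor IMU sessions with ground-truth annotations.

The generator emulates the structure the classifier exploits: each body
position puts each sensor in a characteristic orientation relative to
gravity (a unit "up" vector in the sensor frame) and carries
position-specific motion dynamics — rhythmic gait bounce while upright,
alternating ankle bursts while crawling, a slow whole-body sway plus
caregiver-gait component while held, near-stillness while supine or
sitting.  White noise on both signals, per-participant orientation
jitter (a bounded random rotation emulating garment placement
variability), uncoded transition gaps, device clock offsets, and 8 g
synchronization impulses complete the picture.

Sessions follow the guided-activity protocol by default: nine 60-s
elicited activities followed by five minutes of free play in random
5-30 s bouts, with 2-s uncoded transitions between segments and a sync
impulse before and after.  Everything is driven by one seeded
generator, so identical seeds give bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .annotation import CLASSES, DEFAULT_ALIASES, NONE_LABEL, AnnotationTrack, Interval
from .errors import ConfigError
from .sensor_io import LAB3, PROFILES, Recording, SensorTimeseries
from .windowing import AlignedDataset

#: The nine guided activities, in protocol order, with their classes.
GUIDED_ACTIVITIES = (
    "standing", "walking", "crawling", "floor-sitting", "supine",
    "prone", "held-stationary", "held-walking", "highchair",
)


@dataclass(frozen=True)
class Oscillation:
    """A sinusoidal motion component on one axis of one signal."""

    signal: str  # "accel" | "gyro"
    axis: int  # 0..2
    amplitude: float  # g or deg/s
    freq_hz: float


@dataclass(frozen=True)
class Burst:
    """Intermittent oscillation: active for ``duty`` of each cycle."""

    signal: str
    axis: int
    amplitude: float
    freq_hz: float
    duty: float = 0.5
    cycle_hz: float = 0.5


@dataclass
class PositionSignature:
    """How one body-position class looks to each sensor.

    ``gravity`` maps placement to the unit "up" vector the resting
    accelerometer reads in that position; oscillations and bursts map
    placement to motion components (key "all" applies to every
    placement).
    """

    label: str
    gravity: dict[str, np.ndarray]
    oscillations: dict[str, tuple[Oscillation, ...]] = field(default_factory=dict)
    bursts: dict[str, tuple[Burst, ...]] = field(default_factory=dict)
    accel_noise_sd: float = 0.05  # g
    gyro_noise_sd: float = 5.0  # deg/s

    def __post_init__(self) -> None:
        for p, v in self.gravity.items():
            v = np.asarray(v, dtype=float)
            n = np.linalg.norm(v)
            if n == 0:
                raise ConfigError(f"{self.label}/{p}: gravity direction must be nonzero")
            self.gravity[p] = v / n
        if self.accel_noise_sd < 0 or self.gyro_noise_sd < 0:
            raise ConfigError("noise sds must be >= 0")


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


# Up vectors per class for the hip/thigh/ankle segments (sensor frame:
# x anterior, y superior, z lateral-right); left-side placements mirror z.
_SEGMENT_UP = {
    "upright": {"hip": (0.0, 1.0, 0.0), "thigh": (0.15, 0.99, 0.0), "ankle": (0.05, 1.0, 0.0)},
    "sitting": {"hip": (0.35, 0.94, 0.0), "thigh": (0.95, 0.31, 0.0), "ankle": (0.6, 0.45, 0.66)},
    "supine": {"hip": (0.99, 0.1, 0.0), "thigh": (0.97, 0.24, 0.0), "ankle": (0.95, 0.31, 0.0)},
    "prone": {"hip": (-0.99, 0.1, 0.0), "thigh": (-0.95, -0.31, 0.0), "ankle": (-0.85, -0.2, 0.49)},
    "held": {"hip": (0.45, 0.78, 0.43), "thigh": (0.6, 0.5, 0.62), "ankle": (0.3, 0.6, 0.74)},
}

AX, AY, AZ = 0, 1, 2  # accel/gyro axis indices (roll/pitch/yaw for gyro)


def _segment_kind(placement: str) -> str:
    return placement.split("_", 1)[1]


def _gravity_for(label: str, placement: str) -> np.ndarray:
    v = np.array(_SEGMENT_UP[label][_segment_kind(placement)], dtype=float)
    if placement.startswith("left_"):
        v = v * np.array([1.0, 1.0, -1.0])
    return _unit(v)


def default_signatures(
    placements: tuple[str, ...] = LAB3,
    accel_noise_sd: float = 0.05,
    gyro_noise_sd: float = 5.0,
) -> dict[str, PositionSignature]:
    """Default class signatures for a placement set.

    Supine and prone differ by the sign of gravity on the anterior
    axis; sitting and upright differ mainly in thigh/hip orientation;
    held adds a ~0.8 Hz whole-body sway plus a caregiver-gait
    component; prone (crawling) and upright (gait) carry strong
    intermittent ankle gyro bursts.
    """
    ankles = tuple(p for p in placements if p.endswith("ankle"))
    sigs: dict[str, PositionSignature] = {}
    for label in CLASSES:
        gravity = {p: _gravity_for(label, p) for p in placements}
        osc: dict[str, tuple[Oscillation, ...]] = {}
        bursts: dict[str, tuple[Burst, ...]] = {}
        if label == "upright":
            osc["all"] = (Oscillation("accel", AY, 0.12, 2.0),)
            for p in ankles:
                bursts[p] = (Burst("gyro", AY, 140.0, 2.0, duty=0.5),)
            for p in placements:
                if p.endswith("thigh"):
                    bursts[p] = (Burst("gyro", AY, 80.0, 2.0, duty=0.5),)
        elif label == "sitting":
            osc["all"] = (Oscillation("accel", AX, 0.03, 0.5),)
            for p in ankles:
                bursts[p] = (Burst("gyro", AZ, 15.0, 1.0, duty=0.2),)
        elif label == "supine":
            osc["all"] = (Oscillation("accel", AX, 0.02, 0.3),)
            for p in ankles:
                bursts[p] = (Burst("gyro", AX, 40.0, 1.5, duty=0.3),)
        elif label == "prone":
            osc["all"] = (Oscillation("accel", AX, 0.15, 1.5),)
            for p in ankles:
                bursts[p] = (Burst("gyro", AX, 150.0, 1.5, duty=0.5),)
        elif label == "held":
            osc["all"] = (
                Oscillation("accel", AZ, 0.12, 0.8),
                Oscillation("accel", AY, 0.08, 1.8),
                Oscillation("gyro", AX, 10.0, 0.8),
            )
        sigs[label] = PositionSignature(
            label=label, gravity=gravity, oscillations=osc, bursts=bursts,
            accel_noise_sd=accel_noise_sd, gyro_noise_sd=gyro_noise_sd,
        )
    return sigs


@dataclass(frozen=True)
class ScheduleEntry:
    activity: str  # verbose activity code; maps to a class via the alias table
    duration_s: float

    @property
    def label(self) -> str:
        return DEFAULT_ALIASES.get(self.activity, self.activity)


@dataclass
class SessionSchedule:
    """The ordered activities of one session plus its timing frame.

    Segments are separated by ``gap_s`` uncoded transitions; sync
    impulses sit ``sync_offset_s`` into the lead-in and lead-out.
    """

    entries: tuple[ScheduleEntry, ...]
    gap_s: float = 2.0
    lead_in_s: float = 6.0
    lead_out_s: float = 6.0
    sync_offset_s: float = 2.0
    jitter_deg: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.duration_s <= 0:
                raise ConfigError("segment durations must be positive")

    def segments(self) -> list[tuple[float, float, str, str]]:
        """(onset, offset, activity, class) per segment, session clock."""
        out = []
        t = self.lead_in_s
        for e in self.entries:
            out.append((t, t + e.duration_s, e.activity, e.label))
            t += e.duration_s + self.gap_s
        return out

    @property
    def total_s(self) -> float:
        segs = self.segments()
        return segs[-1][1] + self.gap_s + self.lead_out_s if segs else self.lead_in_s + self.lead_out_s

    @property
    def opening_sync_s(self) -> float:
        return self.sync_offset_s

    @property
    def closing_sync_s(self) -> float:
        return self.total_s - self.lead_out_s + self.sync_offset_s


def default_guided_schedule(
    seed: int | None = 0,
    ability: str = "standard",
    free_play_s: float = 300.0,
    bout_range_s: tuple[float, float] = (5.0, 30.0),
    jitter_deg: float = 10.0,
) -> SessionSchedule:
    """The guided-activity protocol plus randomized free play.

    Nine 60-s elicited activities (standing, walking, crawling, floor
    sitting, supine, prone, held stationary, held walking, highchair),
    then ``free_play_s`` seconds of random position bouts of 5-30 s.
    The "young" ability profile omits upright activities (a pre-standing
    infant) from both parts.
    """
    rng = np.random.default_rng(seed)
    guided = list(GUIDED_ACTIVITIES)
    if ability == "young":
        guided = [a for a in guided if DEFAULT_ALIASES.get(a, a) != "upright"]
    elif ability != "standard":
        raise ConfigError(f"unknown ability profile {ability!r}")
    entries = [ScheduleEntry(a, 60.0) for a in guided]
    pool = guided
    remaining = free_play_s
    while remaining > 0:
        dur = float(rng.uniform(*bout_range_s))
        dur = min(dur, remaining)
        activity = str(pool[rng.integers(len(pool))])
        entries.append(ScheduleEntry(activity, dur))
        remaining -= dur
    return SessionSchedule(entries=tuple(entries), jitter_deg=jitter_deg, seed=seed)


@dataclass
class SimulatedSession:
    """One simulated participant session with full ground truth."""

    recording: Recording
    track: AnnotationTrack  # video time base
    truth_grid: np.ndarray  # session clock
    truth_labels: np.ndarray
    schedule: SessionSchedule
    sensor_sync_opening: dict[str, float]  # raw device clock
    sensor_sync_closing: dict[str, float]
    video_sync_opening: float
    video_sync_closing: float
    seed: int | None


def _random_rotation(rng: np.random.Generator, max_deg: float) -> Rotation:
    if max_deg <= 0:
        return Rotation.identity()
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_deg))
    return Rotation.from_rotvec(axis * angle)


def simulate_session(
    schedule: SessionSchedule,
    signatures: dict[str, PositionSignature] | None = None,
    placements: tuple[str, ...] = LAB3,
    rate: float = 50.0,
    seed: int | None = 0,
) -> SimulatedSession:
    """Render a schedule into raw sensor streams plus annotations.

    Per sample: accel = (jitter-rotated) gravity up-vector + sinusoidal
    motion + white noise; gyro = bursts/oscillations + noise.  Sensors
    get independent device-clock offsets, 8 g impulses at the scheduled
    sync times, and the annotation track mirrors the schedule with
    transition gaps uncoded on a shifted video clock.
    """
    signatures = signatures if signatures is not None else default_signatures(placements)
    segments = schedule.segments()
    missing = {lab for _, _, _, lab in segments} - set(signatures)
    if missing:
        raise ConfigError(f"no signature for scheduled classes: {sorted(missing)}")
    for sig in signatures.values():
        lacking = set(placements) - set(sig.gravity)
        if lacking:
            raise ConfigError(f"signature {sig.label!r} lacks placements {sorted(lacking)}")

    rng = np.random.default_rng(seed)
    rot = _random_rotation(rng, schedule.jitter_deg)
    n = int(round(schedule.total_s * rate)) + 1
    grid = np.arange(n) / rate

    # per-sample segment membership (transition gaps -> -1)
    seg_idx = np.full(n, -1, dtype=int)
    truth = np.full(n, NONE_LABEL, dtype=object)
    for k, (on, off, _, lab) in enumerate(segments):
        m = (grid >= on) & (grid < off)
        seg_idx[m] = k
        truth[m] = lab

    # fill gaps with the neighbouring segment for signal continuity
    fill = seg_idx.copy()
    last = 0
    for i in range(n):
        if fill[i] >= 0:
            last = fill[i]
        else:
            fill[i] = last

    sensors: dict[str, SensorTimeseries] = {}
    sensor_open: dict[str, float] = {}
    sensor_close: dict[str, float] = {}
    open_i = int(round(schedule.opening_sync_s * rate))
    close_i = int(round(schedule.closing_sync_s * rate))

    # random per-segment phases shared across placements, per component
    phases = rng.uniform(0.0, 2 * np.pi, size=(len(segments), 8))

    for p in placements:
        accel = np.empty((n, 3))
        gyro = np.empty((n, 3))
        noise_a = rng.normal(size=(n, 3))
        noise_g = rng.normal(size=(n, 3))
        for k in range(len(segments)):
            lab = segments[k][3]
            sig = signatures[lab]
            m = fill == k
            tm = grid[m]
            in_gap = seg_idx[m] < 0  # transition samples borrow the signature
            a = np.tile(sig.gravity[p], (m.sum(), 1))
            g = np.zeros((m.sum(), 3))
            comps = list(sig.oscillations.get("all", ())) + list(sig.oscillations.get(p, ()))
            comps_b = list(sig.bursts.get("all", ())) + list(sig.bursts.get(p, ()))
            for ci, o in enumerate(comps):
                wave = o.amplitude * np.sin(2 * np.pi * o.freq_hz * tm + phases[k, ci % 8])
                (a if o.signal == "accel" else g)[:, o.axis] += wave
            for ci, b in enumerate(comps_b):
                envelope = ((b.cycle_hz * tm + phases[k, (ci + 4) % 8] / (2 * np.pi)) % 1.0) < b.duty
                wave = b.amplitude * np.sin(2 * np.pi * b.freq_hz * tm + phases[k, ci % 8]) * envelope
                (a if b.signal == "accel" else g)[:, b.axis] += wave
            # transitions: extra movement noise, blended orientation left as-is
            a += sig.accel_noise_sd * noise_a[m] * np.where(in_gap, 3.0, 1.0)[:, None]
            g += sig.gyro_noise_sd * noise_g[m] * np.where(in_gap, 3.0, 1.0)[:, None]
            accel[m] = a
            gyro[m] = g
        # sync impulses: 8 g spikes (two samples) along the current up vector
        for idx in (open_i, close_i):
            direction = _unit(accel[idx])
            accel[idx] = direction * 8.0
            if idx + 1 < n:
                accel[idx + 1] = direction * 4.0
        accel = rot.apply(accel)
        gyro = rot.apply(gyro)
        offset = float(rng.uniform(5.0, 60.0))
        sensors[p] = SensorTimeseries(
            placement=p,
            timestamps=offset + grid,
            accel=accel,
            gyro=gyro,
            nominal_rate=rate,
        )
        sensor_open[p] = offset + grid[open_i]
        sensor_close[p] = offset + grid[close_i]

    video_offset = float(rng.uniform(5.0, 60.0))
    events = [
        Interval(video_offset + on, video_offset + off, lab)
        for on, off, _, lab in segments
    ]
    track = AnnotationTrack(coder_id="truth", events=events, time_base="video")
    recording = Recording(
        sensors=sensors,
        session_id=f"sim-{seed}",
        config_profile=next((k for k, v in PROFILES.items() if v == tuple(placements)), "custom"),
    )
    return SimulatedSession(
        recording=recording,
        track=track,
        truth_grid=grid,
        truth_labels=truth,
        schedule=schedule,
        sensor_sync_opening=sensor_open,
        sensor_sync_closing=sensor_close,
        video_sync_opening=video_offset + grid[open_i],
        video_sync_closing=video_offset + grid[close_i],
        seed=seed,
    )


def make_reliability_track(
    track: AnnotationTrack, seed: int = 0, max_shift_s: float = 0.2
) -> AnnotationTrack:
    """A second-coder track: boundaries jittered by up to ``max_shift_s``.

    Emulates the small onset/offset disagreements real reliability
    coders produce, without changing any label.
    """
    rng = np.random.default_rng(seed)
    events = []
    prev_off = -np.inf
    for e in track.events:
        onset = e.onset + float(rng.uniform(-max_shift_s, max_shift_s))
        offset = e.offset + float(rng.uniform(-max_shift_s, max_shift_s))
        onset = max(onset, prev_off)
        offset = max(offset, onset + 1e-3)
        events.append(Interval(onset, offset, e.label))
        prev_off = offset
    return AnnotationTrack(coder_id="reliability", events=events, time_base=track.time_base)


@dataclass
class SimulatedParticipant:
    participant_id: str
    ability: str
    session: SimulatedSession


def simulate_cohort(
    n_participants: int = 15,
    ability_profiles: list[str] | None = None,
    placements: tuple[str, ...] = LAB3,
    rate: float = 50.0,
    seed: int = 0,
    jitter_deg: float = 10.0,
    free_play_s: float = 300.0,
) -> list[SimulatedParticipant]:
    """Simulate a cohort of guided-protocol sessions with distinct seeds.

    Ability profiles ("standard" or "young") control which positions a
    participant can produce; every participant gets an independent
    schedule randomization, orientation jitter and noise stream.
    """
    if ability_profiles is None:
        ability_profiles = ["standard"] * n_participants
    if len(ability_profiles) != n_participants:
        raise ConfigError("ability_profiles length must equal n_participants")
    children = np.random.SeedSequence(seed).spawn(n_participants)
    cohort = []
    for i, (ability, ss) in enumerate(zip(ability_profiles, children)):
        sub = int(ss.generate_state(1)[0] % (2**31 - 1))
        schedule = default_guided_schedule(
            seed=sub, ability=ability, free_play_s=free_play_s, jitter_deg=jitter_deg
        )
        session = simulate_session(
            schedule, placements=placements, rate=rate, seed=sub
        )
        cohort.append(SimulatedParticipant(f"P{i + 1:02d}", ability, session))
    return cohort


def aligned_from_session(session: SimulatedSession, rate: float | None = None) -> AlignedDataset:
    """Ground-truth shortcut: align a simulated session using the known
    sync times instead of detection (useful for isolating later stages)."""
    from .synchronize import align_session

    return align_session(
        session.recording,
        events=session.sensor_sync_opening,
        video_event_time=session.video_sync_opening,
        track=session.track,
        rate=rate or session.recording.nominal_rate,
    )
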