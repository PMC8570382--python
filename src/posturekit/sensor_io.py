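"""Reading, cleaning and resampling raw per-sensor IMU streams.

Each wearable IMU exports one CSV (or an accel/gyro pair) with a device
timestamp, 3-axis acceleration and 3-axis angular velocity.  Device
clocks are left untouched here — clock alignment is the synchronize
module's job — but rows are cleaned (sorted, de-duplicated, non-numeric
rows dropped) and the jittery Bluetooth timestamps can be resampled
onto an exactly uniform grid by linear interpolation.  Dropouts longer
than a configurable gap are never interpolated across; samples inside
them are flagged invalid and the flag propagates to windowing.

Acceleration is carried in g (1 g = 9.81 m/s^2) and angular velocity in
deg/s throughout the package; dialects declare the unit conversions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, InsufficientDataError

log = logging.getLogger(__name__)

G_PER_MS2 = 1.0 / 9.81

#: Recognized sensor placements.
PLACEMENTS = ("right_hip", "right_thigh", "right_ankle", "left_hip", "left_ankle")
#: 3-sensor lab configuration (strap-on sensors, right side).
LAB3 = ("right_hip", "right_thigh", "right_ankle")
#: 4-sensor home configuration (sensors sewn into leggings, both legs).
HOME4 = ("right_hip", "left_hip", "right_ankle", "left_ankle")

PROFILES = {"lab3": LAB3, "home4": HOME4}

#: Channel order used everywhere: accel XYZ then gyro roll/pitch/yaw.
CHANNELS = ("accel_x", "accel_y", "accel_z", "gyro_roll", "gyro_pitch", "gyro_yaw")


@dataclass(frozen=True)
class Dialect:
    """Column layout and units of one device's CSV export."""

    name: str
    time_column: str
    accel_columns: tuple[str, str, str]
    gyro_columns: tuple[str, str, str]
    time_unit: str = "s"  # "s" | "ms"
    accel_unit: str = "g"  # "g" | "m/s2"


METAMOTION = Dialect(
    name="metamotion",
    time_column="epoch_ms",
    accel_columns=("ax", "ay", "az"),
    gyro_columns=("gx", "gy", "gz"),
    time_unit="ms",
    accel_unit="g",
)

BIOSTAMP = Dialect(
    name="biostamp",
    time_column="timestamp_ms",
    accel_columns=("accel_x", "accel_y", "accel_z"),
    gyro_columns=("gyro_x", "gyro_y", "gyro_z"),
    time_unit="ms",
    accel_unit="m/s2",
)

DIALECTS = {"metamotion": METAMOTION, "biostamp": BIOSTAMP}


@dataclass
class QCSummary:
    n_rows: int
    n_nonnumeric_dropped: int
    n_duplicates_dropped: int
    n_reordered: int


@dataclass
class SensorTimeseries:
    """One placement's cleaned 6-channel IMU stream.

    Timestamps are seconds relative to the file start, strictly
    increasing; ``valid`` flags samples that are trustworthy (False
    inside bridged-over dropouts after resampling).
    """

    placement: str
    timestamps: np.ndarray
    accel: np.ndarray  # (n, 3), g
    gyro: np.ndarray  # (n, 3), deg/s
    nominal_rate: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    qc: QCSummary | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.timestamps.shape, dtype=bool)
        if len(self.accel) != len(self.gyro) or len(self.accel) != len(self.timestamps):
            raise FormatError("accel, gyro and timestamps must have identical length")
        if self.nominal_rate <= 0:
            raise FormatError("nominal_rate must be positive")
        if np.any(np.diff(self.timestamps) <= 0):
            raise FormatError("timestamps must be strictly increasing after cleaning")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0]) if len(self) else 0.0

    def channels(self) -> np.ndarray:
        """(n, 6) array in canonical channel order."""
        return np.hstack([self.accel, self.gyro])

    def shifted(self, dt: float) -> "SensorTimeseries":
        return replace(self, timestamps=self.timestamps + dt)


@dataclass
class Recording:
    """A session's sensors, keyed by placement; all share one nominal rate."""

    sensors: dict[str, SensorTimeseries]
    session_id: str = ""
    config_profile: str = "custom"

    def __post_init__(self) -> None:
        rates = {s.nominal_rate for s in self.sensors.values()}
        if len(rates) > 1:
            raise FormatError(f"sensors disagree on nominal rate: {sorted(rates)}")

    @property
    def placements(self) -> tuple[str, ...]:
        return tuple(self.sensors)

    @property
    def nominal_rate(self) -> float:
        return next(iter(self.sensors.values())).nominal_rate


def _detect_rate(timestamps: np.ndarray) -> float:
    dt = np.median(np.diff(timestamps))
    rate = 1.0 / dt
    # snap to the common device rates when within 2%
    for nominal in (50.0, 62.5):
        if abs(rate - nominal) / nominal < 0.02:
            return nominal
    return float(rate)


def read_sensor_csv(
    path,
    dialect: Dialect | str = METAMOTION,
    placement: str = "right_hip",
) -> SensorTimeseries:
    """Read and clean one sensor CSV.

    Non-numeric rows are rejected and counted, rows are sorted by time,
    duplicate timestamps collapse to the first occurrence, and the
    nominal rate is detected from the median sample spacing.  A QC
    summary (rows read / dropped) is logged and attached.
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    needed = [dialect.time_column, *dialect.accel_columns, *dialect.gyro_columns]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing} for dialect {dialect.name!r}")
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    numeric = df[needed].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    n_bad = int(bad.sum())
    numeric = numeric[~bad]
    if numeric.empty:
        raise EmptyInputError(f"{path}: no numeric rows")

    t = numeric[dialect.time_column].to_numpy(float)
    n_reordered = int((np.diff(t) < 0).sum())
    order = np.argsort(t, kind="stable")
    numeric = numeric.iloc[order]
    t = t[order]
    keep = np.concatenate([[True], np.diff(t) > 0])
    n_dup = int((~keep).sum())
    numeric = numeric[keep]
    t = t[keep]

    if dialect.time_unit == "ms":
        t = t * 1e-3
    t = t - t[0]
    accel = numeric[list(dialect.accel_columns)].to_numpy(float)
    if dialect.accel_unit == "m/s2":
        accel = accel * G_PER_MS2
    gyro = numeric[list(dialect.gyro_columns)].to_numpy(float)

    qc = QCSummary(len(df), n_bad, n_dup, n_reordered)
    log.info(
        "%s: %d rows read, %d non-numeric dropped, %d duplicates collapsed",
        path, qc.n_rows, qc.n_nonnumeric_dropped, qc.n_duplicates_dropped,
    )
    rate = _detect_rate(t) if len(t) > 1 else 50.0
    return SensorTimeseries(
        placement=placement, timestamps=t, accel=accel, gyro=gyro,
        nominal_rate=rate, qc=qc,
    )


def read_biostamp_pair(accel_path, gyro_path, placement: str = "right_hip") -> SensorTimeseries:
    """Merge the split accel/gyro exports of a leggings sensor on timestamp.

    Rows are joined on the (ms) timestamp; rows present in only one
    file are dropped.
    """
    a = pd.read_csv(accel_path)
    g = pd.read_csv(gyro_path)
    a.columns = [c.strip().lower() for c in a.columns]
    g.columns = [c.strip().lower() for c in g.columns]
    tcol = BIOSTAMP.time_column
    for df, cols, path in ((a, BIOSTAMP.accel_columns, accel_path), (g, BIOSTAMP.gyro_columns, gyro_path)):
        missing = [c for c in (tcol, *cols) if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
    merged = a.merge(g, on=tcol, how="inner")
    if merged.empty:
        raise EmptyInputError("accel and gyro files share no timestamps")
    import io

    buf = io.StringIO()
    merged.to_csv(buf, index=False)
    buf.seek(0)
    return read_sensor_csv(buf, dialect=BIOSTAMP, placement=placement)


def resample_uniform(
    series: SensorTimeseries, rate: float, max_gap_s: float = 0.5
) -> SensorTimeseries:
    """Linearly interpolate every channel onto a uniform grid.

    The grid spans first to last timestamp at exactly ``1/rate``
    spacing.  Grid samples falling strictly inside an input gap longer
    than ``max_gap_s`` are flagged invalid rather than interpolated:
    long dropouts must not fabricate motion.
    """
    if len(series) < 2:
        raise InsufficientDataError("resampling needs at least 2 samples")
    if rate <= 0:
        raise ValueError("rate must be positive")
    t = series.timestamps
    n = int(np.floor((t[-1] - t[0]) * rate + 1e-9)) + 1
    grid = t[0] + np.arange(n) / rate
    chans = series.channels()
    out = np.column_stack([np.interp(grid, t, chans[:, j]) for j in range(6)])
    valid = np.ones(n, dtype=bool)
    gaps = np.flatnonzero(np.diff(t) > max_gap_s)
    for i in gaps:
        valid &= ~((grid > t[i]) & (grid < t[i + 1]))
    # propagate input invalid flags to the nearest grid samples
    if not series.valid.all():
        bad_idx = np.searchsorted(grid, t[~series.valid])
        for k in bad_idx:
            valid[max(k - 1, 0):k + 1] = False
    return SensorTimeseries(
        placement=series.placement,
        timestamps=grid,
        accel=out[:, :3],
        gyro=out[:, 3:],
        nominal_rate=rate,
        valid=valid,
        qc=series.qc,
    )


def write_aligned_csv(ds, path) -> None:
    """Write an aligned dataset as the internal wide CSV.

    Columns: t_s, valid, label[, label_reliability], then 6 channels per
    placement.  Values are written at 9 significant digits so a
    write→read round trip reproduces them exactly at that precision.
    """
    cols: dict[str, object] = {"t_s": ds.grid, "valid": ds.valid.astype(int)}
    cols["label"] = ds.labels_primary
    if ds.labels_reliability is not None:
        cols["label_reliability"] = ds.labels_reliability
    for placement in ds.placements:
        block = ds.data[placement]
        for j, ch in enumerate(CHANNELS):
            cols[f"{placement}_{ch}"] = block[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.9g")


def read_aligned_csv(path):
    """Read the internal aligned-dataset CSV written by ``write_aligned_csv``."""
    from .windowing import AlignedDataset  # deferred: windowing owns the type

    df = pd.read_csv(path)
    placements = []
    for col in df.columns:
        for p in PLACEMENTS:
            if col == f"{p}_{CHANNELS[0]}" and p not in placements:
                placements.append(p)
    if not placements:
        raise FormatError(f"{path}: no placement channel columns found")
    grid = df["t_s"].to_numpy(float)
    rate = 1.0 / float(np.median(np.diff(grid))) if len(grid) > 1 else 50.0
    data = {
        p: df[[f"{p}_{ch}" for ch in CHANNELS]].to_numpy(float) for p in placements
    }
    rel = (
        df["label_reliability"].astype(object).to_numpy()
        if "label_reliability" in df.columns
        else None
    )
    return AlignedDataset(
        grid=grid,
        rate=rate,
        data=data,
        valid=df["valid"].to_numpy(bool),
        labels_primary=df["label"].astype(object).to_numpy(),
        labels_reliability=rel,
    )
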