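import numpy as np
import pytest

from posturekit.sensor_io import LAB3
from posturekit.synthetic import (
    ScheduleEntry,
    SessionSchedule,
    default_signatures,
    simulate_session,
)
from posturekit.windowing import AlignedDataset


def make_dataset(
    duration_s: float,
    rate: float = 50.0,
    labels=None,
    placements=("right_hip",),
    valid=None,
    fill=0.0,
):
    """Minimal aligned dataset for windowing/feature tests."""
    n = int(round(duration_s * rate)) + 1
    grid = np.arange(n) / rate
    data = {p: np.full((n, 6), fill, dtype=float) for p in placements}
    if labels is None:
        labels = np.full(n, "sitting", dtype=object)
    else:
        labels = np.asarray(labels, dtype=object)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return AlignedDataset(
        grid=grid, rate=rate, data=data, valid=valid,
        labels_primary=labels, labels_reliability=None,
    )


def quiet_signatures(placements=LAB3):
    """Noise- and motion-free signatures: pure gravity orientation."""
    sigs = default_signatures(placements, accel_noise_sd=0.0, gyro_noise_sd=0.0)
    for sig in sigs.values():
        sig.oscillations = {}
        sig.bursts = {}
    return sigs


def short_schedule(seed=0, jitter_deg=0.0):
    """A five-bout schedule (~3 min) covering every class, for fast tests."""
    entries = tuple(
        ScheduleEntry(a, 30.0)
        for a in ("held-stationary", "supine", "floor-sitting", "prone", "standing")
    )
    return SessionSchedule(entries=entries, jitter_deg=jitter_deg, seed=seed)


@pytest.fixture(scope="session")
def short_session():
    """One short simulated session with default noise, no jitter."""
    return simulate_session(short_schedule(seed=11), seed=11)


@pytest.fixture(scope="session")
def quiet_session():
    """Short noise-free, motion-free session: exact gravity vectors."""
    return simulate_session(
        short_schedule(seed=3), signatures=quiet_signatures(), seed=3
    )
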