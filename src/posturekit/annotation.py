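"""Interval-coded body-position annotations.

Human coders mark the onset and offset of each body-position bout
(supine, prone, sitting, upright, held) from video.  This module parses
those interval exports, samples them onto a uniform time grid so every
IMU sample carries a label, merges information from a second
(reliability) coder, and masks spans when the sensor garment was off.

Intervals are half-open ``[onset, offset)`` in seconds.  Spans that are
uncoded — transitions between positions, garment-off periods, anything
outside the five-class vocabulary — carry the sentinel label ``none``
and never contribute to training or agreement statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, UndefinedMetricError

log = logging.getLogger(__name__)

#: The five trainable body-position classes, in canonical order.
CLASSES: tuple[str, ...] = ("supine", "prone", "sitting", "upright", "held")

#: Sentinel for uncoded / transition / masked samples.
NONE_LABEL = "none"

#: Default mapping from verbose activity codes onto the five classes.
#: Crawling counts as prone (stomach-down locomotion); standing, walking
#: and cruising are upright; lap / highchair / floor sitting are sitting;
#: held covers carried positions whether the caregiver is still or moving.
DEFAULT_ALIASES: dict[str, str] = {
    "supine": "supine",
    "prone": "prone",
    "crawling": "prone",
    "sitting": "sitting",
    "floor-sitting": "sitting",
    "lap-sitting": "sitting",
    "highchair": "sitting",
    "restrained-seat": "sitting",
    "upright": "upright",
    "standing": "upright",
    "walking": "upright",
    "cruising": "upright",
    "held": "held",
    "held-stationary": "held",
    "held-walking": "held",
}


@dataclass(frozen=True)
class Interval:
    onset: float
    offset: float
    label: str

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class AnnotationTrack:
    """One coder's interval-coded position events.

    Events are half-open ``[onset, offset)`` seconds, non-overlapping and
    sorted; gaps between events are uncoded.  ``time_base`` records
    whether times are on the video clock (pre-synchronization) or the
    aligned sensor clock.
    """

    coder_id: str
    events: list[Interval]
    time_base: str = "video"  # "video" | "sensor"

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset)
        for ev in self.events:
            if not ev.offset > ev.onset:
                raise FormatError(
                    f"coder {self.coder_id}: event [{ev.onset}, {ev.offset}) "
                    "has offset <= onset"
                )
        for prev, nxt in zip(self.events, self.events[1:]):
            if nxt.onset < prev.offset:
                raise FormatError(
                    f"coder {self.coder_id}: overlapping events at "
                    f"[{prev.onset}, {prev.offset}) and [{nxt.onset}, {nxt.offset})"
                )

    def shifted(self, dt: float) -> "AnnotationTrack":
        """Return a copy with every onset/offset shifted by ``dt`` seconds."""
        return AnnotationTrack(
            coder_id=self.coder_id,
            events=[Interval(e.onset + dt, e.offset + dt, e.label) for e in self.events],
            time_base="sensor",
        )

    @property
    def total_coded_s(self) -> float:
        return float(sum(e.duration for e in self.events))


@dataclass
class RemovalLog:
    """Caregiver-reported intervals when the sensor garment was off."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end, _ in self.intervals:
            if not end > start:
                raise FormatError(f"removal interval [{start}, {end}) has end <= start")

    def shifted(self, dt: float) -> "RemovalLog":
        return RemovalLog([(s + dt, e + dt, r) for s, e, r in self.intervals])


def _normalize_code(code: str, aliases: Mapping[str, str]) -> str:
    key = str(code).strip().lower().replace("_", "-").replace(" ", "-")
    label = aliases.get(key, key)
    if label not in CLASSES:
        log.warning("annotation code %r outside the five-class vocabulary; mapped to none", code)
        return NONE_LABEL
    return label


def read_annotation_csv(
    path,
    time_unit: str = "s",
    aliases: Mapping[str, str] | None = None,
    coder_id: str = "primary",
    time_base: str = "video",
) -> AnnotationTrack:
    """Read a Datavyu-style interval export (columns onset, offset, code).

    ``time_unit`` is ``"ms"`` or ``"s"``; output is always seconds.
    Codes outside the five-class vocabulary map through the alias table,
    and anything still unrecognized becomes ``none`` with a warning.
    """
    if time_unit not in ("ms", "s"):
        raise FormatError(f"time_unit must be 'ms' or 's', got {time_unit!r}")
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"onset", "offset", "code"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing)}")
    if df.empty:
        raise EmptyInputError(f"{path}: no annotation rows")
    scale = 1e-3 if time_unit == "ms" else 1.0
    aliases = dict(DEFAULT_ALIASES if aliases is None else aliases)
    events = []
    for i, row in df.iterrows():
        onset = float(row["onset"]) * scale
        offset = float(row["offset"]) * scale
        if not offset > onset:
            raise FormatError(f"{path} row {i}: offset {offset} <= onset {onset}")
        events.append(Interval(onset, offset, _normalize_code(row["code"], aliases)))
    return AnnotationTrack(coder_id=coder_id, events=events, time_base=time_base)


def read_removal_log_csv(path, time_unit: str = "s") -> RemovalLog:
    """Read a removal-log CSV with columns start, end[, reason]."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"start", "end"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing removal-log columns {sorted(missing)}")
    scale = 1e-3 if time_unit == "ms" else 1.0
    reasons = df["reason"] if "reason" in df.columns else [""] * len(df)
    return RemovalLog(
        [
            (float(s) * scale, float(e) * scale, str(r))
            for s, e, r in zip(df["start"], df["end"], reasons)
        ]
    )


def sample_labels(track: AnnotationTrack, grid: np.ndarray) -> np.ndarray:
    """Label every grid time with its containing interval's class.

    Half-open convention: a grid point exactly at an offset belongs to
    the *next* interval (or is uncoded).  Output length always equals
    the grid length; uncovered samples get ``none``.
    """
    grid = np.asarray(grid, dtype=float)
    out = np.full(grid.shape, NONE_LABEL, dtype=object)
    if not track.events:
        return out
    onsets = np.array([e.onset for e in track.events])
    offsets = np.array([e.offset for e in track.events])
    labels = np.array([e.label for e in track.events], dtype=object)
    idx = np.searchsorted(onsets, grid, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(grid.shape, dtype=bool)
    inside[ok] = grid[ok] < offsets[idx[ok]]
    out[inside] = labels[idx[inside]]
    return out


def interrater_agreement(
    a: AnnotationTrack, b: AnnotationTrack, grid: np.ndarray
) -> tuple[float, float]:
    """Per-sample agreement between two coders on a shared grid.

    Samples where either coder is uncoded are excluded.  Returns
    ``(percent_agreement, kappa)`` with agreement on a 0-100 scale.
    """
    from .evaluate import cohen_kappa  # local import to avoid a cycle

    la = sample_labels(a, grid)
    lb = sample_labels(b, grid)
    both = (la != NONE_LABEL) & (lb != NONE_LABEL)
    n = int(both.sum())
    if n == 0:
        raise UndefinedMetricError("no samples coded by both coders")
    agreement = 100.0 * float((la[both] == lb[both]).mean())
    kappa = cohen_kappa(la[both], lb[both])
    return agreement, kappa


def disagreement_mask(
    a: AnnotationTrack, b: AnnotationTrack | None, grid: np.ndarray
) -> np.ndarray:
    """True where both coders coded a sample but assigned different classes.

    With no reliability coder the mask is all False (single-coder mode).
    """
    grid = np.asarray(grid, dtype=float)
    if b is None:
        log.info("no reliability coder; disagreement mask empty")
        return np.zeros(grid.shape, dtype=bool)
    la = sample_labels(a, grid)
    lb = sample_labels(b, grid)
    both = (la != NONE_LABEL) & (lb != NONE_LABEL)
    return both & (la != lb)


def apply_removal_log(
    labels: Sequence, log_: RemovalLog, grid: np.ndarray
) -> np.ndarray:
    """Force samples inside garment-off intervals to ``none``."""
    out = np.asarray(labels, dtype=object).copy()
    grid = np.asarray(grid, dtype=float)
    for start, end, _ in log_.intervals:
        out[(grid >= start) & (grid < end)] = NONE_LABEL
    return out
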