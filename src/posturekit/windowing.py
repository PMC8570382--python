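"""Sliding-window segmentation of an aligned session.

The aligned multi-sensor stream is cut into overlapping windows
(default 4 s long, stepped every 1 s, so 200 samples at 50 Hz) and each
window gets a body-position label only when a single class covers at
least 75% of its samples (the "3 of 4 seconds" rule).  Windows spanning
coder disagreement or invalid sensor samples are excluded, carrying the
reason, so downstream training can filter on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .annotation import NONE_LABEL

log = logging.getLogger(__name__)


class ExclusionReason(str, Enum):
    NONE = "none"
    NO_MAJORITY = "no_majority"
    CODER_DISAGREEMENT = "coder_disagreement"
    INVALID_SAMPLES = "invalid_samples"


@dataclass
class AlignedDataset:
    """Uniform-grid multi-sensor matrix with per-sample labels.

    ``grid`` is the shared aligned clock (s, sync event at 0); ``data``
    maps placement to an (n, 6) block in canonical channel order;
    ``labels_primary``/``labels_reliability`` are per-sample position
    labels from the coder track(s).
    """

    grid: np.ndarray
    rate: float
    data: dict[str, np.ndarray]
    valid: np.ndarray
    labels_primary: np.ndarray
    labels_reliability: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.grid)
        for p, block in self.data.items():
            if block.shape != (n, 6):
                raise ValueError(f"placement {p}: block shape {block.shape} != ({n}, 6)")
        for name in ("valid", "labels_primary"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != grid length")
        if self.labels_reliability is not None and len(self.labels_reliability) != n:
            raise ValueError("labels_reliability length != grid length")

    @property
    def placements(self) -> tuple[str, ...]:
        return tuple(self.data)

    def __len__(self) -> int:
        return len(self.grid)


@dataclass
class LabeledWindow:
    """One 4-s snippet: per-placement sample block plus its label.

    ``samples`` maps placement to a (window_len, 6) view; ``label`` is a
    position class or None when the window is excluded.
    """

    start: float
    index: int  # first sample index in the aligned grid
    length: int
    samples: dict[str, np.ndarray]
    label: str | None
    excluded_reason: ExclusionReason = ExclusionReason.NONE

    @property
    def excluded(self) -> bool:
        return self.excluded_reason is not ExclusionReason.NONE


def assign_window_label(
    labels: np.ndarray, min_coverage: float = 0.75
) -> tuple[str | None, ExclusionReason]:
    """Majority label of a window under the coverage rule.

    A class is assigned iff it covers at least ``min_coverage`` of the
    window's samples (3 of 4 s at the default); uncoded samples never
    count toward any class.  Otherwise the window is excluded for
    lacking a majority.
    """
    labels = np.asarray(labels, dtype=object)
    need = min_coverage * len(labels)
    values, counts = np.unique(labels[labels != NONE_LABEL], return_counts=True)
    if len(values):
        best = int(np.argmax(counts))
        if counts[best] >= need:
            return str(values[best]), ExclusionReason.NONE
    return None, ExclusionReason.NO_MAJORITY


def extract_windows(
    ds: AlignedDataset,
    window_s: float = 4.0,
    step_s: float = 1.0,
    min_coverage: float = 0.75,
) -> list[LabeledWindow]:
    """Slice the aligned dataset into overlapping labeled windows.

    Windows start at the grid start (the sync event) and every
    ``step_s`` thereafter while a full window fits, giving
    floor((T - window_s)/step_s) + 1 windows.  Windows containing any
    invalid sensor sample are excluded.
    """
    if not window_s >= step_s > 0:
        raise ValueError("need window_s >= step_s > 0")
    wlen = int(round(window_s * ds.rate))
    step = int(round(step_s * ds.rate))
    n = len(ds)
    if n < wlen:
        log.warning("dataset (%d samples) shorter than one window (%d)", n, wlen)
        return []
    windows: list[LabeledWindow] = []
    for i in range(0, n - wlen + 1, step):
        sl = slice(i, i + wlen)
        samples = {p: ds.data[p][sl] for p in ds.placements}
        if not ds.valid[sl].all():
            label, reason = None, ExclusionReason.INVALID_SAMPLES
        else:
            label, reason = assign_window_label(ds.labels_primary[sl], min_coverage)
        windows.append(
            LabeledWindow(
                start=float(ds.grid[i]),
                index=i,
                length=wlen,
                samples=samples,
                label=label,
                excluded_reason=reason,
            )
        )
    return windows


def apply_disagreement_exclusion(
    windows: list[LabeledWindow], mask: np.ndarray
) -> list[LabeledWindow]:
    """Exclude every window containing a coder-disagreement sample.

    ``mask`` is the per-sample boolean disagreement mask on the aligned
    grid.  Already-excluded windows keep their original reason.
    """
    mask = np.asarray(mask, dtype=bool)
    out = []
    for w in windows:
        if not w.excluded and mask[w.index:w.index + w.length].any():
            out.append(
                LabeledWindow(
                    start=w.start, index=w.index, length=w.length,
                    samples=w.samples, label=None,
                    excluded_reason=ExclusionReason.CODER_DISAGREEMENT,
                )
            )
        else:
            out.append(w)
    return out


def window_table(windows: list[LabeledWindow]) -> pd.DataFrame:
    """Summary table: one row per window (start_s, label, excluded_reason)."""
    return pd.DataFrame(
        {
            "start_s": [w.start for w in windows],
            "label": [w.label for w in windows],
            "excluded_reason": [w.excluded_reason.value for w in windows],
        }
    )
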