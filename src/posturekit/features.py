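"""Per-window motion features.

For every placement × signal (accel/gyro) × axis channel, ten summary
statistics are computed over the window's samples: mean, standard
deviation (n-1), skew (Fisher–Pearson g1), excess kurtosis (g2),
minimum, median, maximum, 25th and 75th percentiles
(linear interpolation), and sum.  With the 3-sensor lab profile that is
10 × 3 × 2 × 3 = 180 base features.

On top of those, cross-sensor and cross-axis aggregates of per-channel
window sums — the plain sum and the root-sum-of-squares "magnitude" —
add 2 × (signals × axes) + 2 × (placements × signals) features
(24 for the lab profile, total 204).  Pairwise axis/sensor correlation
and mean-absolute-difference groups exist as optional extensions,
disabled by default.

The registry fixes the feature order and a hash of it is stamped into
trained models, so a model can refuse feature tables built under a
different registry.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigError
from .sensor_io import PROFILES
from .windowing import LabeledWindow

STAT_NAMES = ("mean", "sd", "skew", "kurtosis", "min", "median", "max", "p25", "p75", "sum")
SIGNALS = ("accel", "gyro")
AXES = {"accel": ("x", "y", "z"), "gyro": ("roll", "pitch", "yaw")}

#: Conventions string folded into the registry hash so models trained
#: under different statistic definitions can never be mixed.
CONVENTIONS = "sd:ddof1;skew:g1;kurtosis:excess-g2;percentile:linear;magnitude:rss-of-window-sums"


@dataclass(frozen=True)
class FeatureEntry:
    name: str
    kind: str  # base_stat | cross_sensor_sum | cross_sensor_magnitude |
    #            cross_axis_sum | cross_axis_magnitude |
    #            axis_correlation | sensor_correlation |
    #            axis_difference | sensor_difference
    placements: tuple[str, ...]
    signal: str
    axes: tuple[str, ...]
    statistic: str = ""


@dataclass
class FeatureRegistry:
    """Ordered, named feature definitions for one sensor profile."""

    entries: tuple[FeatureEntry, ...]
    profile: str
    placements: tuple[str, ...]
    enabled_groups: tuple[str, ...]

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def size(self) -> int:
        return len(self.entries)

    @property
    def n_base(self) -> int:
        return sum(1 for e in self.entries if e.kind == "base_stat")

    @property
    def hash(self) -> str:
        h = hashlib.sha256()
        h.update(CONVENTIONS.encode())
        for name in self.names:
            h.update(name.encode())
        return h.hexdigest()[:16]

    def manifest(self) -> dict:
        return {
            "profile": self.profile,
            "placements": list(self.placements),
            "conventions": CONVENTIONS,
            "enabled_groups": list(self.enabled_groups),
            "n_features": self.size,
            "names": self.names,
            "hash": self.hash,
        }


def build_registry(
    profile: str = "lab3",
    placements: tuple[str, ...] | None = None,
    include_correlations: bool = False,
    include_differences: bool = False,
) -> FeatureRegistry:
    """Construct the feature registry for a sensor profile.

    ``profile`` is "lab3", "home4" or "custom" (the latter requires an
    explicit placement tuple).  Default groups are the base statistics
    plus the cross-sensor/cross-axis sum and magnitude aggregates.
    """
    if placements is None:
        if profile not in PROFILES:
            raise ConfigError(f"profile {profile!r} needs an explicit placements tuple")
        placements = PROFILES[profile]
    placements = tuple(placements)
    if not placements:
        raise ConfigError("at least one placement required")

    entries: list[FeatureEntry] = []
    groups = ["base_stat", "cross_sensor", "cross_axis"]
    for p in placements:
        for sig in SIGNALS:
            for ax in AXES[sig]:
                for stat in STAT_NAMES:
                    entries.append(
                        FeatureEntry(f"{p}_{sig}_{ax}_{stat}", "base_stat", (p,), sig, (ax,), stat)
                    )
    # cross-sensor aggregates of per-channel window sums (need >= 2 sensors)
    if len(placements) > 1:
        for sig in SIGNALS:
            for ax in AXES[sig]:
                entries.append(
                    FeatureEntry(f"all_{sig}_{ax}_sum", "cross_sensor_sum", placements, sig, (ax,))
                )
        for sig in SIGNALS:
            for ax in AXES[sig]:
                entries.append(
                    FeatureEntry(
                        f"all_{sig}_{ax}_magnitude", "cross_sensor_magnitude", placements, sig, (ax,)
                    )
                )
    # cross-axis aggregates within each sensor
    for p in placements:
        for sig in SIGNALS:
            entries.append(
                FeatureEntry(f"{p}_{sig}_axes_sum", "cross_axis_sum", (p,), sig, AXES[sig])
            )
    for p in placements:
        for sig in SIGNALS:
            entries.append(
                FeatureEntry(f"{p}_{sig}_axes_magnitude", "cross_axis_magnitude", (p,), sig, AXES[sig])
            )
    if include_correlations:
        groups.append("correlations")
        for p in placements:
            for sig in SIGNALS:
                for a1, a2 in combinations(AXES[sig], 2):
                    entries.append(
                        FeatureEntry(f"{p}_{sig}_{a1}_{a2}_corr", "axis_correlation", (p,), sig, (a1, a2))
                    )
        for p1, p2 in combinations(placements, 2):
            for sig in SIGNALS:
                for ax in AXES[sig]:
                    entries.append(
                        FeatureEntry(f"{p1}_{p2}_{sig}_{ax}_corr", "sensor_correlation", (p1, p2), sig, (ax,))
                    )
    if include_differences:
        groups.append("differences")
        for p in placements:
            for sig in SIGNALS:
                for a1, a2 in combinations(AXES[sig], 2):
                    entries.append(
                        FeatureEntry(f"{p}_{sig}_{a1}_{a2}_absdiff", "axis_difference", (p,), sig, (a1, a2))
                    )
        for p1, p2 in combinations(placements, 2):
            for sig in SIGNALS:
                for ax in AXES[sig]:
                    entries.append(
                        FeatureEntry(f"{p1}_{p2}_{sig}_{ax}_absdiff", "sensor_difference", (p1, p2), sig, (ax,))
                    )
    return FeatureRegistry(tuple(entries), profile, placements, tuple(groups))


def _base_stats_block(x: np.ndarray) -> np.ndarray:
    """Ten statistics per channel for a batch of windows.

    ``x`` is (n_windows, window_len, n_channels); returns
    (n_windows, n_channels, 10) in STAT_NAMES order.  Central moments
    are computed directly; on a zero-variance channel skew and kurtosis
    are defined as 0 rather than NaN.
    """
    n = x.shape[1]
    mean = x.mean(axis=1)
    d = x - mean[:, None, :]
    m2 = (d**2).mean(axis=1)
    m3 = (d**3).mean(axis=1)
    m4 = (d**4).mean(axis=1)
    sd = np.sqrt(m2 * n / (n - 1)) if n > 1 else np.zeros_like(m2)
    # a channel is zero-variance when its spread is at rounding-noise scale
    scale = np.abs(x).max(axis=1)
    nonzero = m2 > (1e-10 * (scale + 1e-30)) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(nonzero, m3 / np.where(nonzero, m2, 1) ** 1.5, 0.0)
        kurt = np.where(nonzero, m4 / np.where(nonzero, m2, 1) ** 2 - 3.0, 0.0)
    q = np.percentile(x, [0, 25, 50, 75, 100], axis=1)  # linear interpolation
    total = x.sum(axis=1)
    return np.stack(
        [mean, sd, skew, kurt, q[0], q[2], q[4], q[1], q[3], total], axis=-1
    )


def _window_matrix(window: LabeledWindow, placements: tuple[str, ...]) -> np.ndarray:
    try:
        return np.stack([window.samples[p] for p in placements], axis=1)  # (len, n_p, 6)
    except KeyError as exc:
        raise ConfigError(f"window lacks placement {exc} required by the registry") from exc


def _compute_batch(x: np.ndarray, registry: FeatureRegistry) -> np.ndarray:
    """Feature matrix for a batch of stacked windows.

    ``x`` is (n_windows, window_len, n_placements, 6) with channels in
    canonical order; returns (n_windows, registry.size) aligned to the
    registry entry order.
    """
    nw, wlen, npl, _ = x.shape
    placements = registry.placements
    flat = x.reshape(nw, wlen, npl * 6)
    base = _base_stats_block(flat)  # (nw, npl*6, 10)
    sums = base[:, :, STAT_NAMES.index("sum")].reshape(nw, npl, 6)

    chan_index = {}
    for pi, p in enumerate(placements):
        for si, sig in enumerate(SIGNALS):
            for ai, ax in enumerate(AXES[sig]):
                chan_index[(p, sig, ax)] = (pi, si * 3 + ai)

    cols: list[np.ndarray] = []
    for e in registry.entries:
        if e.kind == "base_stat":
            pi, ci = chan_index[(e.placements[0], e.signal, e.axes[0])]
            cols.append(base[:, pi * 6 + ci, STAT_NAMES.index(e.statistic)])
        elif e.kind in ("cross_sensor_sum", "cross_sensor_magnitude"):
            ci = chan_index[(e.placements[0], e.signal, e.axes[0])][1]
            s = sums[:, :, ci]  # (nw, npl)
            cols.append(s.sum(axis=1) if e.kind == "cross_sensor_sum" else np.sqrt((s**2).sum(axis=1)))
        elif e.kind in ("cross_axis_sum", "cross_axis_magnitude"):
            pi = chan_index[(e.placements[0], e.signal, e.axes[0])][0]
            ci = [chan_index[(e.placements[0], e.signal, ax)][1] for ax in e.axes]
            s = sums[:, pi, :][:, ci]  # (nw, 3)
            cols.append(s.sum(axis=1) if e.kind == "cross_axis_sum" else np.sqrt((s**2).sum(axis=1)))
        elif e.kind in ("axis_correlation", "sensor_correlation"):
            if e.kind == "axis_correlation":
                p = e.placements[0]
                i1 = chan_index[(p, e.signal, e.axes[0])]
                i2 = chan_index[(p, e.signal, e.axes[1])]
            else:
                i1 = chan_index[(e.placements[0], e.signal, e.axes[0])]
                i2 = chan_index[(e.placements[1], e.signal, e.axes[0])]
            a = x[:, :, i1[0], i1[1]]
            b = x[:, :, i2[0], i2[1]]
            da = a - a.mean(axis=1, keepdims=True)
            db = b - b.mean(axis=1, keepdims=True)
            denom = np.sqrt((da**2).sum(axis=1) * (db**2).sum(axis=1))
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, (da * db).sum(axis=1) / np.where(denom > 0, denom, 1), 0.0)
            cols.append(r)
        elif e.kind in ("axis_difference", "sensor_difference"):
            if e.kind == "axis_difference":
                p = e.placements[0]
                i1 = chan_index[(p, e.signal, e.axes[0])]
                i2 = chan_index[(p, e.signal, e.axes[1])]
            else:
                i1 = chan_index[(e.placements[0], e.signal, e.axes[0])]
                i2 = chan_index[(e.placements[1], e.signal, e.axes[0])]
            cols.append(np.abs(x[:, :, i1[0], i1[1]] - x[:, :, i2[0], i2[1]]).mean(axis=1))
        else:  # pragma: no cover
            raise ConfigError(f"unknown feature kind {e.kind!r}")
    return np.column_stack(cols)


def base_features(window: LabeledWindow, registry: FeatureRegistry) -> np.ndarray:
    """The base-statistic slice of one window's feature vector."""
    x = _window_matrix(window, registry.placements)[None]
    full = _compute_batch(x, registry)[0]
    mask = [e.kind == "base_stat" for e in registry.entries]
    return full[np.asarray(mask)]


def derived_features(window: LabeledWindow, registry: FeatureRegistry) -> np.ndarray:
    """The derived (cross-sensor/cross-axis) slice of one window's features."""
    x = _window_matrix(window, registry.placements)[None]
    full = _compute_batch(x, registry)[0]
    mask = [e.kind != "base_stat" for e in registry.entries]
    return full[np.asarray(mask)]


def featurize(windows: list[LabeledWindow], registry: FeatureRegistry) -> pd.DataFrame:
    """Feature table for the assignable windows.

    Excluded windows are omitted; rows are ordered by window start.
    The first two columns are ``start_s`` and ``label``; the rest are
    the registry features in registry order.  The registry hash is
    attached in ``DataFrame.attrs["registry_hash"]``.
    """
    kept = sorted((w for w in windows if not w.excluded), key=lambda w: w.start)
    if kept:
        x = np.stack([_window_matrix(w, registry.placements) for w in kept])
        values = _compute_batch(x, registry)
    else:
        values = np.empty((0, registry.size))
    table = pd.DataFrame(values, columns=registry.names)
    table.insert(0, "label", [w.label for w in kept])
    table.insert(0, "start_s", [w.start for w in kept])
    table.attrs["registry_hash"] = registry.hash
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature column names of a table produced by ``featurize``."""
    return [c for c in table.columns if c not in ("start_s", "label")]
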