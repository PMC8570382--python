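"""Session configuration and the file-based staged workflow.

A :class:`SessionConfig` (usually loaded from YAML) declares where the
raw files live, the sensor dialect and profile, windowing and model
parameters, and the seed.  :func:`run_pipeline` executes the requested
stages in order — sync → windows → featurize → train → predict →
evaluate → report — reading each stage's inputs from and writing its
artifacts to the output directory, so a stage can be re-run in
isolation.  Every JSON artifact embeds a provenance block (config hash,
feature-registry hash, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .annotation import DEFAULT_ALIASES, read_annotation_csv, read_removal_log_csv
from .errors import ConfigError, PostureKitError
from .evaluate import evaluation_report, timeline_report
from .features import build_registry, featurize
from .models import ModelSpec, chronological_split, predict, train_individual
from .sensor_io import DIALECTS, PROFILES, Recording, read_sensor_csv, write_aligned_csv, read_aligned_csv
from .synchronize import SyncEvent, align_session, check_drift, detect_sync_impulse
from .windowing import extract_windows, window_table

log = logging.getLogger(__name__)

STAGES = ("sync", "windows", "featurize", "train", "predict", "evaluate", "report")


class SyncConfig(BaseModel):
    search_start_s: float = 0.0
    search_end_s: float = 30.0
    min_prominence_g: float = 2.0
    drift_tolerance_s: float = 0.5
    manual_times: dict[str, float] = Field(default_factory=dict)
    video_event_time_s: float = 0.0
    closing_search_s: float | None = None  # seconds from stream end; None = no check
    closing_video_event_time_s: float | None = None


class ModelConfig(BaseModel):
    n_trees: int = 750
    mtry: int | None = None
    seed: int = 0

    def to_spec(self) -> ModelSpec:
        return ModelSpec(n_trees=self.n_trees, mtry=self.mtry, seed=self.seed)


class PathsConfig(BaseModel):
    sensors: dict[str, str] = Field(default_factory=dict)  # placement -> CSV path
    annotation: str | None = None
    annotation_reliability: str | None = None
    removal_log: str | None = None
    out_dir: str = "posturekit_out"


class SessionConfig(BaseModel):
    """Validated configuration for one session's processing run."""

    session_id: str = "session"
    dialect: str = "metamotion"
    profile: str = "lab3"
    rate: float = 50.0
    window_s: float = 4.0
    step_s: float = 1.0
    min_coverage: float = 0.75
    train_frac: float = 0.6
    annotation_time_unit: str = "s"
    aliases: dict[str, str] = Field(default_factory=lambda: dict(DEFAULT_ALIASES))
    sync: SyncConfig = Field(default_factory=SyncConfig)
    model: ModelConfig = Field(default_factory=ModelConfig)
    paths: PathsConfig = Field(default_factory=PathsConfig)
    seed: int = 0

    @field_validator("dialect")
    @classmethod
    def _known_dialect(cls, v: str) -> str:
        if v not in DIALECTS:
            raise ValueError(f"unknown dialect {v!r}; choose from {sorted(DIALECTS)}")
        return v

    @field_validator("profile")
    @classmethod
    def _known_profile(cls, v: str) -> str:
        if v not in PROFILES and v != "custom":
            raise ValueError(f"unknown profile {v!r}")
        return v

    @field_validator("rate", "window_s", "step_s", "train_frac", "min_coverage")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be positive")
        return v

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def registry(self):
        return build_registry(self.profile) if self.profile != "custom" else build_registry(
            "custom", placements=tuple(self.paths.sensors)
        )

    def provenance(self) -> dict:
        return {
            "session_id": self.session_id,
            "config_hash": self.config_hash,
            "registry_hash": self.registry().hash,
            "seed": self.seed,
        }

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


def _out(config: SessionConfig) -> Path:
    out = Path(config.paths.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_json(path: Path, payload: dict, config: SessionConfig) -> None:
    payload = {"provenance": config.provenance(), **payload}
    path.write_text(json.dumps(payload, indent=2, default=str))


def _stage_sync(config: SessionConfig) -> None:
    if not config.paths.sensors:
        raise ConfigError("sync: no sensor files configured")
    sensors = {
        p: read_sensor_csv(path, dialect=config.dialect, placement=p)
        for p, path in config.paths.sensors.items()
    }
    recording = Recording(sensors=sensors, session_id=config.session_id, config_profile=config.profile)
    opening: dict[str, SyncEvent] = {}
    closing: dict[str, SyncEvent] = {}
    for p, series in sensors.items():
        if p in config.sync.manual_times:
            t = config.sync.manual_times[p]
            opening[p] = SyncEvent(p, t, config.sync.video_event_time_s, "opening", "manual")
        else:
            t0 = series.timestamps[0]
            t = detect_sync_impulse(
                series,
                (t0 + config.sync.search_start_s, t0 + config.sync.search_end_s),
                config.sync.min_prominence_g,
            )
            opening[p] = SyncEvent(p, t, config.sync.video_event_time_s, "opening")
        if config.sync.closing_search_s is not None:
            if config.sync.closing_video_event_time_s is None:
                raise ConfigError("closing_search_s set without closing_video_event_time_s")
            t1 = series.timestamps[-1]
            tc = detect_sync_impulse(
                series, (t1 - config.sync.closing_search_s, t1), config.sync.min_prominence_g
            )
            closing[p] = SyncEvent(p, tc, config.sync.closing_video_event_time_s, "closing")
    track = rel_track = removal = None
    if config.paths.annotation:
        track = read_annotation_csv(
            config.paths.annotation, config.annotation_time_unit, config.aliases
        )
    if config.paths.annotation_reliability:
        rel_track = read_annotation_csv(
            config.paths.annotation_reliability, config.annotation_time_unit,
            config.aliases, coder_id="reliability",
        )
    if config.paths.removal_log:
        removal = read_removal_log_csv(config.paths.removal_log, config.annotation_time_unit)
    ds = align_session(
        recording,
        events=opening,
        video_event_time=config.sync.video_event_time_s,
        track=track,
        reliability_track=rel_track,
        rate=config.rate,
        removal_log=removal,
    )
    out = _out(config)
    write_aligned_csv(ds, out / "aligned.csv")
    drift = check_drift(opening, closing or None, config.sync.drift_tolerance_s)
    _write_json(out / "drift.json", {"drift_report": drift.to_dict()}, config)


def _stage_windows(config: SessionConfig) -> None:
    out = _out(config)
    ds = read_aligned_csv(out / "aligned.csv")
    windows = extract_windows(ds, config.window_s, config.step_s, config.min_coverage)
    window_table(windows).to_csv(out / "windows.csv", index=False)


def _stage_featurize(config: SessionConfig) -> None:
    out = _out(config)
    ds = read_aligned_csv(out / "aligned.csv")
    windows = extract_windows(ds, config.window_s, config.step_s, config.min_coverage)
    registry = config.registry()
    table = featurize(windows, registry)
    table.to_csv(out / "features.csv", index=False)
    (out / "registry.json").write_text(json.dumps(registry.manifest(), indent=2))


def _load_features(config: SessionConfig) -> pd.DataFrame:
    out = _out(config)
    table = pd.read_csv(out / "features.csv")
    table.attrs["registry_hash"] = config.registry().hash
    return table


def _stage_train(config: SessionConfig) -> None:
    import pickle

    out = _out(config)
    table = _load_features(config)
    registry = config.registry()
    train, test = chronological_split(table, config.train_frac)
    model = train_individual(train, registry, config.model.to_spec())
    model.provenance = config.provenance()
    with open(out / "model.pkl", "wb") as fh:
        pickle.dump(model, fh)
    train[["start_s", "label"]].to_csv(out / "train_windows.csv", index=False)
    test[["start_s", "label"]].to_csv(out / "test_windows.csv", index=False)
    _write_json(out / "training_summary.json", {"class_counts": model.training_summary}, config)


def _stage_predict(config: SessionConfig) -> None:
    import pickle

    out = _out(config)
    with open(out / "model.pkl", "rb") as fh:
        model = pickle.load(fh)
    table = _load_features(config)
    test_starts = pd.read_csv(out / "test_windows.csv")["start_s"] if (out / "test_windows.csv").exists() else None
    if test_starts is not None:
        table = table[table["start_s"].isin(test_starts)]
    labels = predict(model, table, config.registry())
    pd.DataFrame(
        {"start_s": table["start_s"].to_numpy(), "actual": table["label"].to_numpy(), "predicted": labels}
    ).to_csv(out / "predictions.csv", index=False)


def _stage_evaluate(config: SessionConfig) -> None:
    out = _out(config)
    preds = pd.read_csv(out / "predictions.csv")
    report = evaluation_report(
        preds["actual"].astype(object), preds["predicted"].astype(object),
        provenance=config.provenance(),
    )
    _write_json(out / "report.json", report.to_dict(), config)
    (out / "report.txt").write_text(report.to_text() + "\n")


def _stage_report(config: SessionConfig) -> None:
    out = _out(config)
    preds = pd.read_csv(out / "predictions.csv")
    removal = (
        read_removal_log_csv(config.paths.removal_log, config.annotation_time_unit)
        if config.paths.removal_log
        else None
    )
    episodes, percents = timeline_report(
        preds["start_s"], preds["predicted"].astype(object), config.step_s, removal
    )
    episodes.to_csv(out / "timeline.csv", index=False)
    _write_json(out / "position_totals.json", {"percent_of_classified_time": percents}, config)


_STAGE_FUNCS = {
    "sync": _stage_sync,
    "windows": _stage_windows,
    "featurize": _stage_featurize,
    "train": _stage_train,
    "predict": _stage_predict,
    "evaluate": _stage_evaluate,
    "report": _stage_report,
}


def run_pipeline(config: SessionConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages in canonical order; returns the out dir.

    Any stage failure is re-raised as a :class:`PostureKitError` naming
    the stage.  Stages are idempotent given identical inputs and seed.
    """
    stages = list(STAGES) if stages is None else [s for s in STAGES if s in stages]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    for stage in stages:
        try:
            log.info("stage %s: running", stage)
            _STAGE_FUNCS[stage](config)
        except PostureKitError as exc:
            raise type(exc)(f"[{stage}] {exc}") from exc
        except FileNotFoundError as exc:
            raise ConfigError(f"[{stage}] missing input: {exc}") from exc
    return _out(config)


def write_simulated_session(session, out_dir, dialect: str = "metamotion") -> Path:
    """Write a simulated session as standard pipeline input files.

    Produces one sensor CSV per placement (metamotion layout: epoch_ms,
    ax..gz), the annotation CSV (onset, offset, code; video clock,
    seconds) and a ground-truth label CSV on the session clock.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p, series in session.recording.sensors.items():
        pd.DataFrame(
            {
                "epoch_ms": series.timestamps * 1e3,
                "ax": series.accel[:, 0], "ay": series.accel[:, 1], "az": series.accel[:, 2],
                "gx": series.gyro[:, 0], "gy": series.gyro[:, 1], "gz": series.gyro[:, 2],
            }
        ).to_csv(out / f"sensor_{p}.csv", index=False, float_format="%.9g")
    pd.DataFrame(
        {
            "onset": [e.onset for e in session.track.events],
            "offset": [e.offset for e in session.track.events],
            "code": [e.label for e in session.track.events],
        }
    ).to_csv(out / "annotation.csv", index=False, float_format="%.9g")
    pd.DataFrame({"t_s": session.truth_grid, "label": session.truth_labels}).to_csv(
        out / "truth.csv", index=False, float_format="%.9g"
    )
    meta = {
        "video_sync_opening_s": session.video_sync_opening,
        "video_sync_closing_s": session.video_sync_closing,
        "seed": session.seed,
        "placements": list(session.recording.placements),
        "rate_hz": session.recording.nominal_rate,
    }
    (out / "session.json").write_text(json.dumps(meta, indent=2))
    return out
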