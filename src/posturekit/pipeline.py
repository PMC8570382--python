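"""End-to-end experiment helpers: session → windows → features → forest → metrics.

These functions wire the pipeline stages together for whole simulated
(or pre-loaded) sessions, and are what the validation experiments, the
acceptance script and the examples drive.  The file-based staged
workflow used by the CLI lives in :mod:`posturekit.config`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import CLASSES
from .evaluate import (
    EvaluationReport,
    confusion_matrix,
    evaluation_report,
    prevalence_correlation,
    prevalence_table,
)
from .features import FeatureRegistry, build_registry, featurize
from .models import ModelSpec, chronological_split, predict, train_group_loso, train_individual
from .synchronize import SyncEvent, check_drift, detect_sync_impulse, align_session
from .synthetic import SimulatedParticipant, SimulatedSession
from .windowing import apply_disagreement_exclusion, extract_windows


@dataclass
class ParticipantResult:
    """Everything the individual-model pipeline produced for one session."""

    participant_id: str
    features: pd.DataFrame
    train: pd.DataFrame
    test: pd.DataFrame
    report: EvaluationReport
    predictions: pd.DataFrame  # start_s, actual, predicted
    actual_prevalence: pd.Series
    predicted_prevalence: pd.Series


def detect_session_syncs(
    session: SimulatedSession, search_s: float = 30.0, min_prominence_g: float = 2.0
) -> tuple[dict[str, SyncEvent], dict[str, SyncEvent]]:
    """Detect opening and closing impulses in every sensor of a session."""
    opening, closing = {}, {}
    for p, series in session.recording.sensors.items():
        t0, t1 = series.timestamps[0], series.timestamps[-1]
        t_open = detect_sync_impulse(series, (t0, t0 + search_s), min_prominence_g)
        t_close = detect_sync_impulse(series, (t1 - search_s, t1), min_prominence_g)
        opening[p] = SyncEvent(p, t_open, session.video_sync_opening, "opening")
        closing[p] = SyncEvent(p, t_close, session.video_sync_closing, "closing")
    return opening, closing


def session_feature_table(
    session: SimulatedSession,
    registry: FeatureRegistry,
    window_s: float = 4.0,
    step_s: float = 1.0,
    min_coverage: float = 0.75,
    reliability_track=None,
    detect_sync: bool = True,
) -> pd.DataFrame:
    """Sync, align, window and featurize one session."""
    if detect_sync:
        opening, _ = detect_session_syncs(session)
        events: dict = opening
    else:
        events = session.sensor_sync_opening
    ds = align_session(
        session.recording,
        events=events,
        video_event_time=session.video_sync_opening,
        track=session.track,
        reliability_track=reliability_track,
    )
    windows = extract_windows(ds, window_s=window_s, step_s=step_s, min_coverage=min_coverage)
    if reliability_track is not None:
        from .annotation import disagreement_mask

        mask = disagreement_mask(
            session.track.shifted(-session.video_sync_opening),
            reliability_track.shifted(-session.video_sync_opening),
            ds.grid,
        )
        windows = apply_disagreement_exclusion(windows, mask)
    return featurize(windows, registry)


def run_individual_pipeline(
    participant: SimulatedParticipant,
    registry: FeatureRegistry | None = None,
    spec: ModelSpec | None = None,
    train_frac: float = 0.6,
    **window_kwargs,
) -> ParticipantResult:
    """Full individual-model validation for one simulated participant."""
    registry = registry or build_registry("lab3")
    spec = spec or ModelSpec()
    table = session_feature_table(participant.session, registry, **window_kwargs)
    train, test = chronological_split(table, train_frac)
    model = train_individual(train, registry, spec)
    predicted = predict(model, test, registry)
    actual = test["label"].to_numpy(dtype=object)
    report = evaluation_report(actual, predicted)
    return ParticipantResult(
        participant_id=participant.participant_id,
        features=table,
        train=train,
        test=test,
        report=report,
        predictions=pd.DataFrame(
            {"start_s": test["start_s"].to_numpy(), "actual": actual, "predicted": predicted}
        ),
        actual_prevalence=prevalence_table(actual),
        predicted_prevalence=prevalence_table(predicted),
    )


@dataclass
class CohortResult:
    """Individual-model validation across a cohort, plus optional LOSO."""

    individual: dict[str, ParticipantResult]
    pooled_confusion: pd.DataFrame
    prevalence_r_per_class: dict[str, float]
    prevalence_r_pooled: float
    loso_reports: dict[str, EvaluationReport] | None = None

    @property
    def individual_accuracy_mean(self) -> float:
        return float(np.mean([r.report.accuracy for r in self.individual.values()]))

    @property
    def individual_kappa_mean(self) -> float:
        return float(np.mean([r.report.kappa for r in self.individual.values()]))

    @property
    def loso_accuracy_mean(self) -> float:
        if not self.loso_reports:
            raise ValueError("no LOSO results in this cohort run")
        return float(np.mean([r.accuracy for r in self.loso_reports.values()]))

    def pooled_class_sensitivity(self) -> pd.Series:
        from .evaluate import class_metrics

        return class_metrics(self.pooled_confusion)["sensitivity"]


def run_cohort_experiment(
    cohort: list[SimulatedParticipant],
    registry: FeatureRegistry | None = None,
    spec: ModelSpec | None = None,
    train_frac: float = 0.6,
    loso_ids: list[str] | None = None,
) -> CohortResult:
    """Individual models for every participant; LOSO for a chosen subset.

    ``loso_ids`` selects the participants included in the
    leave-one-subject-out comparison (None skips LOSO; group training at
    750 trees is the pipeline's dominant cost, so the comparison can run
    on a sub-cohort).
    """
    registry = registry or build_registry("lab3")
    spec = spec or ModelSpec()
    individual: dict[str, ParticipantResult] = {}
    for participant in cohort:
        individual[participant.participant_id] = run_individual_pipeline(
            participant, registry, spec, train_frac
        )

    all_actual = np.concatenate([r.predictions["actual"].to_numpy(object) for r in individual.values()])
    all_pred = np.concatenate([r.predictions["predicted"].to_numpy(object) for r in individual.values()])
    pooled = confusion_matrix(all_actual, all_pred, classes=[c for c in CLASSES if c in set(all_actual) | set(all_pred)])

    actual_props = pd.DataFrame({pid: r.actual_prevalence for pid, r in individual.items()}).T
    pred_props = pd.DataFrame({pid: r.predicted_prevalence for pid, r in individual.items()}).T
    per_class_r, pooled_r = prevalence_correlation(actual_props, pred_props)

    loso_reports = None
    if loso_ids:
        tables = {pid: individual[pid].features for pid in loso_ids}
        loso = train_group_loso(tables, registry, spec)
        loso_reports = {
            pid: evaluation_report(preds["actual"], preds["predicted"])
            for pid, (_, preds) in loso.items()
        }
    return CohortResult(
        individual=individual,
        pooled_confusion=pooled,
        prevalence_r_per_class=per_class_r,
        prevalence_r_pooled=pooled_r,
        loso_reports=loso_reports,
    )


def verify_session_sync(session: SimulatedSession) -> dict:
    """Impulse-recovery and drift check against a session's ground truth.

    Returns per-sensor absolute recovery error (in samples) for the
    opening impulse and the drift report from the opening/closing pair.
    """
    opening, closing = detect_session_syncs(session)
    rate = session.recording.nominal_rate
    errors = {
        p: abs(opening[p].sensor_time - session.sensor_sync_opening[p]) * rate
        for p in opening
    }
    drift = check_drift(opening, closing)
    return {"recovery_error_samples": errors, "drift": drift}
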