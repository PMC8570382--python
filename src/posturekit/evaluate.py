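"""Validation metrics for window-level position classification.

Everything downstream of prediction lives here: the confusion matrix,
overall accuracy, Cohen's kappa with Landis–Koch verbal bins, per-class
sensitivity (recall) and positive predictive value (precision),
prevalence, actual-vs-predicted prevalence correlations (per
participant or per fixed-length time interval), the paired-t comparison
of model types, and a full-day timeline summary of predictions.

Kappa, sensitivity and PPV are computed from first principles here; the
test suite cross-checks them against independent implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import CLASSES, NONE_LABEL, RemovalLog
from .errors import InsufficientDataError, UndefinedMetricError

#: Landis & Koch verbal ranges for kappa, applied after rounding to 2 decimals.
LANDIS_KOCH_BINS = (
    (0.81, "Almost Perfect"),
    (0.61, "Substantial"),
    (0.41, "Moderate"),
    (0.21, "Fair"),
    (-np.inf, "Slight to Poor"),
)


def confusion_matrix(actual, predicted, classes=None) -> pd.DataFrame:
    """Class-by-class counts: rows = actual, columns = predicted."""
    actual = np.asarray(actual, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    if classes is None:
        observed = set(actual) | set(predicted)
        classes = [c for c in CLASSES if c in observed]
        classes += sorted(observed - set(classes))
    mat = pd.DataFrame(0, index=list(classes), columns=list(classes), dtype=int)
    for a, p in zip(actual, predicted):
        mat.loc[a, p] += 1
    mat.index.name = "actual"
    mat.columns.name = "predicted"
    return mat


def accuracy(confusion: pd.DataFrame) -> float:
    total = confusion.values.sum()
    if total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    return float(np.trace(confusion.values) / total)


def cohen_kappa(actual, predicted) -> float:
    """Unweighted Cohen's kappa: (po - pe) / (1 - pe).

    po is the observed agreement fraction; pe the chance agreement
    expected from the two marginal distributions.  Undefined when both
    sequences are constant and identical (pe = 1).
    """
    actual = np.asarray(actual, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if actual.size == 0:
        raise UndefinedMetricError("kappa undefined for empty sequences")
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    conf = confusion_matrix(actual, predicted)
    return kappa_from_confusion(conf)


def kappa_from_confusion(confusion: pd.DataFrame) -> float:
    counts = confusion.values.astype(float)
    n = counts.sum()
    po = np.trace(counts) / n
    pe = float((counts.sum(axis=1) * counts.sum(axis=0)).sum()) / n**2
    if pe >= 1.0:
        raise UndefinedMetricError("kappa undefined: chance agreement pe = 1")
    return float((po - pe) / (1.0 - pe))


def class_metrics(confusion: pd.DataFrame) -> pd.DataFrame:
    """Per-class prevalence (%), sensitivity and PPV from a confusion matrix.

    PPV is NaN (missing, not zero) for classes the model never
    predicted; sensitivity is NaN for classes that never occurred.
    """
    counts = confusion.values.astype(float)
    total = counts.sum()
    actual_n = counts.sum(axis=1)
    predicted_n = counts.sum(axis=0)
    tp = np.diag(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        sensitivity = np.where(actual_n > 0, tp / actual_n, np.nan)
        ppv = np.where(predicted_n > 0, tp / predicted_n, np.nan)
    return pd.DataFrame(
        {
            "prevalence": 100.0 * actual_n / total,
            "sensitivity": sensitivity,
            "ppv": ppv,
            "n_actual": actual_n.astype(int),
            "n_predicted": predicted_n.astype(int),
        },
        index=confusion.index,
    )


def landis_koch_bin(kappa: float) -> str:
    """Verbal agreement bin for a kappa value.

    The value is first rounded half-up to 2 decimals (so 0.805 counts as
    0.81, Almost Perfect); negative kappa falls in Slight to Poor.
    """
    k = float(Decimal(repr(float(kappa))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    for lo, name in LANDIS_KOCH_BINS:
        if k >= lo:
            return name
    return LANDIS_KOCH_BINS[-1][1]  # pragma: no cover


@dataclass
class EvaluationReport:
    """Window-level validation summary for one testing set."""

    confusion: pd.DataFrame
    accuracy: float
    kappa: float
    per_class: pd.DataFrame
    n_windows: int
    provenance: dict = field(default_factory=dict)

    @property
    def kappa_bin(self) -> str:
        return landis_koch_bin(self.kappa)

    def to_dict(self) -> dict:
        return {
            "n_windows": self.n_windows,
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "kappa_bin": self.kappa_bin,
            "classes": list(self.confusion.index),
            "confusion": self.confusion.values.tolist(),
            "per_class": {
                cls: {
                    k: (None if pd.isna(v) else float(v))
                    for k, v in row.items()
                }
                for cls, row in self.per_class.iterrows()
            },
            "provenance": self.provenance,
        }

    def to_text(self) -> str:
        lines = [
            f"windows: {self.n_windows}",
            f"overall accuracy: {self.accuracy:.2f}",
            f"kappa: {self.kappa:.2f} ({self.kappa_bin})",
            "",
            f"{'position':<10}{'prev %':>8}{'sens':>8}{'ppv':>8}",
        ]
        for cls, row in self.per_class.iterrows():
            sens = "--" if pd.isna(row["sensitivity"]) else f"{row['sensitivity']:.2f}"
            ppv = "--" if pd.isna(row["ppv"]) else f"{row['ppv']:.2f}"
            lines.append(f"{cls:<10}{row['prevalence']:>8.2f}{sens:>8}{ppv:>8}")
        return "\n".join(lines)


def evaluation_report(actual, predicted, provenance: dict | None = None) -> EvaluationReport:
    """Build the full validation report for one set of predictions."""
    conf = confusion_matrix(actual, predicted)
    try:
        kappa = kappa_from_confusion(conf)
    except UndefinedMetricError:
        kappa = float("nan")
    return EvaluationReport(
        confusion=conf,
        accuracy=accuracy(conf),
        kappa=kappa,
        per_class=class_metrics(conf),
        n_windows=int(conf.values.sum()),
        provenance=provenance or {},
    )


def prevalence_table(labels, classes=CLASSES) -> pd.Series:
    """Fraction of windows in each class (ignores ``none``)."""
    labels = np.asarray(labels, dtype=object)
    labels = labels[labels != NONE_LABEL]
    n = max(len(labels), 1)
    return pd.Series({c: float((labels == c).sum()) / n for c in classes})


def interval_prevalence(
    starts, labels, interval_s: float = 450.0, classes=CLASSES
) -> pd.DataFrame:
    """Per-interval class proportions from window labels.

    The timeline is partitioned into fixed-length bins (default 7.5 min)
    by window start time; each row is one bin's label proportions.
    """
    starts = np.asarray(starts, dtype=float)
    labels = np.asarray(labels, dtype=object)
    keep = labels != NONE_LABEL
    starts, labels = starts[keep], labels[keep]
    if starts.size == 0:
        return pd.DataFrame(columns=list(classes))
    bins = np.floor(starts / interval_s).astype(int)
    rows = {}
    for b in np.unique(bins):
        rows[b] = prevalence_table(labels[bins == b], classes)
    return pd.DataFrame(rows).T.sort_index()


def prevalence_correlation(
    actual_props: pd.DataFrame, predicted_props: pd.DataFrame
) -> tuple[dict[str, float], float]:
    """Pearson r between actual and predicted class proportions.

    Inputs are aligned tables (units × classes) where a unit is a
    participant or a time interval.  Returns per-class r (NaN when a
    class's actual or predicted proportions have zero variance) and the
    pooled r across all class × unit pairs.
    """
    actual_props, predicted_props = actual_props.align(predicted_props, join="inner")
    if len(actual_props) < 3:
        raise InsufficientDataError("need >= 3 paired proportion observations")
    per_class: dict[str, float] = {}
    for cls in actual_props.columns:
        a = actual_props[cls].to_numpy(float)
        p = predicted_props[cls].to_numpy(float)
        if np.std(a) == 0 or np.std(p) == 0:
            per_class[cls] = float("nan")
        else:
            per_class[cls] = float(stats.pearsonr(a, p).statistic)
    a_all = actual_props.to_numpy(float).ravel()
    p_all = predicted_props.to_numpy(float).ravel()
    if np.std(a_all) == 0 or np.std(p_all) == 0:
        pooled = float("nan")
    else:
        pooled = float(stats.pearsonr(a_all, p_all).statistic)
    return per_class, pooled


@dataclass
class PairedTReport:
    t: float
    df: int
    p: float
    mean_first: float
    mean_second: float
    sd_first: float
    sd_second: float

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "means": [round(self.mean_first, 2), round(self.mean_second, 2)],
            "sds": [self.sd_first, self.sd_second],
        }


def compare_model_types(first, second) -> PairedTReport:
    """Two-sided paired t-test between per-participant metric pairs.

    The statistic is computed on ``first - second``; df = n - 1.
    """
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if first.shape != second.shape or first.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D sequences")
    if first.size < 2:
        raise InsufficientDataError("paired t needs >= 2 pairs")
    if np.std(first - second) == 0:
        raise UndefinedMetricError("paired t undefined: all differences equal")
    res = stats.ttest_rel(first, second)
    return PairedTReport(
        t=float(res.statistic),
        df=int(first.size - 1),
        p=float(res.pvalue),
        mean_first=float(first.mean()),
        mean_second=float(second.mean()),
        sd_first=float(first.std(ddof=1)),
        sd_second=float(second.std(ddof=1)),
    )


def timeline_report(
    starts,
    labels,
    step_s: float = 1.0,
    removal_log: RemovalLog | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Merge per-window predictions into a day timeline.

    Contiguous windows with the same label become one episode; garment
    removal intervals appear as gaps (label ``none``).  Returns the
    episode table (start_s, end_s, label) and each class's percent of
    classified time.
    """
    starts = np.asarray(starts, dtype=float)
    labels = np.asarray(labels, dtype=object).copy()
    order = np.argsort(starts)
    starts, labels = starts[order], labels[order]
    if removal_log is not None:
        for s, e, _ in removal_log.intervals:
            labels[(starts >= s) & (starts < e)] = NONE_LABEL
    episodes = []
    for t, lab in zip(starts, labels):
        if episodes and episodes[-1][2] == lab and abs(episodes[-1][1] - t) <= 1.5 * step_s:
            episodes[-1][1] = t + step_s
        else:
            episodes.append([t, t + step_s, lab])
    table = pd.DataFrame(episodes, columns=["start_s", "end_s", "label"])
    classified = table[table["label"] != NONE_LABEL]
    dur = (classified["end_s"] - classified["start_s"]).groupby(classified["label"]).sum()
    total = float(dur.sum()) if len(dur) else 1.0
    percents = {c: 100.0 * float(dur.get(c, 0.0)) / total for c in CLASSES}
    return table, percents
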