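"""Random-forest body-position classifiers.

Two training regimes mirror the intended uses of the method:

* **individual** — a model per participant, trained on the
  chronologically first 60% of that participant's windows *within each
  class* (so every position the infant showed is represented) and
  tested on the remaining 40%.  This mimics coding video at the start
  of a day and predicting the rest of the day.
* **group (leave-one-subject-out)** — for each participant, a model
  trained on all other participants' full sessions predicts the
  held-out participant's windows.

The forest itself is scikit-learn's ``RandomForestClassifier`` with 750
trees and mtry = floor(sqrt(n_features)); seeded training makes runs
reproducible, and a golden-seed regression test pins the library's
behavior.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigError, DegenerateModelError, EmptyInputError, InsufficientDataError
from .features import FeatureRegistry, feature_columns

log = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Forest hyperparameters; defaults follow the validated pipeline."""

    n_trees: int = 750
    mtry: int | None = None  # None -> floor(sqrt(n_features))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigError("n_trees must be >= 1")

    def resolved_mtry(self, n_features: int) -> int:
        m = self.mtry if self.mtry is not None else int(math.floor(math.sqrt(n_features)))
        if not 1 <= m <= n_features:
            raise ConfigError(f"mtry {m} outside [1, {n_features}]")
        return m


@dataclass
class TrainedModel:
    """A fitted forest plus the metadata needed to use it safely."""

    forest: RandomForestClassifier
    registry_hash: str
    classes: tuple[str, ...]
    training_summary: dict[str, int]
    spec: ModelSpec
    provenance: dict = field(default_factory=dict)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def chronological_split(
    table: pd.DataFrame, train_frac: float = 0.6
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-class chronological train/test split.

    Within each class, windows sorted by start time; the first
    round(train_frac * n) go to training, the rest to testing.  A class
    with a single window goes entirely to training (with a warning) so
    the model still knows it exists.
    """
    if table.empty:
        raise EmptyInputError("no labeled windows to split")
    train_parts, test_parts = [], []
    for label, group in table.groupby("label", sort=False):
        group = group.sort_values("start_s")
        n = len(group)
        k = _round_half_up(train_frac * n)
        if n == 1:
            log.warning("class %r has a single window; assigned entirely to training", label)
            k = 1
        train_parts.append(group.iloc[:k])
        test_parts.append(group.iloc[k:])
    train = pd.concat(train_parts).sort_values("start_s")
    test = pd.concat(test_parts).sort_values("start_s") if test_parts else table.iloc[0:0]
    train.attrs.update(table.attrs)
    test.attrs.update(table.attrs)
    return train, test


def _check_registry(table: pd.DataFrame, registry: FeatureRegistry) -> None:
    got = table.attrs.get("registry_hash")
    if got is not None and got != registry.hash:
        raise ConfigError(
            f"feature table registry hash {got} != model registry hash {registry.hash}"
        )


def train_individual(
    table: pd.DataFrame, registry: FeatureRegistry, spec: ModelSpec | None = None
) -> TrainedModel:
    """Fit a forest on one participant's (training) feature table.

    The class list is exactly the classes present in the training data
    — positions an infant never showed (e.g. upright in a pre-stander)
    are simply absent from the model.
    """
    spec = spec or ModelSpec()
    _check_registry(table, registry)
    if table.empty:
        raise EmptyInputError("empty training table")
    y = table["label"].to_numpy(dtype=object)
    classes = tuple(pd.unique(y))
    if len(classes) < 2:
        raise DegenerateModelError(
            f"training data contains a single class {classes}; cannot fit a classifier"
        )
    cols = feature_columns(table)
    X = table[cols].to_numpy(float)
    forest = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=spec.resolved_mtry(len(cols)),
        random_state=spec.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    summary = {str(c): int((y == c).sum()) for c in classes}
    return TrainedModel(
        forest=forest,
        registry_hash=registry.hash,
        classes=tuple(forest.classes_),
        training_summary=summary,
        spec=spec,
    )


def predict(
    model: TrainedModel,
    table: pd.DataFrame,
    registry: FeatureRegistry | None = None,
    return_votes: bool = False,
):
    """Classify each feature-table row; optionally return vote fractions.

    Refuses tables built under a different feature registry than the
    model was trained with.
    """
    got = table.attrs.get("registry_hash")
    expected = registry.hash if registry is not None else model.registry_hash
    if got is not None and got != expected or (
        registry is not None and registry.hash != model.registry_hash
    ):
        raise ConfigError("feature table registry does not match the trained model")
    cols = [c for c in table.columns if c not in ("start_s", "label")]
    if table.empty:
        labels = np.empty(0, dtype=object)
        return (labels, pd.DataFrame(columns=model.classes)) if return_votes else labels
    X = table[cols].to_numpy(float)
    labels = model.forest.predict(X).astype(object)
    if return_votes:
        votes = pd.DataFrame(model.forest.predict_proba(X), columns=model.forest.classes_)
        return labels, votes
    return labels


def train_group_loso(
    tables: dict[str, pd.DataFrame],
    registry: FeatureRegistry,
    spec: ModelSpec | None = None,
) -> dict[str, tuple[TrainedModel, pd.DataFrame]]:
    """Leave-one-subject-out group models.

    For each participant, a model is trained on the *full* labeled
    sessions of all other participants and applied to the held-out
    participant's windows.  Returns, per participant, the model and a
    prediction table (start_s, actual, predicted).
    """
    spec = spec or ModelSpec()
    if len(tables) < 2:
        raise InsufficientDataError("leave-one-subject-out needs >= 2 participants")
    out: dict[str, tuple[TrainedModel, pd.DataFrame]] = {}
    for held_out in tables:
        train_table = pd.concat(
            [t for pid, t in tables.items() if pid != held_out], ignore_index=True
        )
        train_table.attrs["registry_hash"] = registry.hash
        model = train_individual(train_table, registry, spec)
        test = tables[held_out]
        predicted = predict(model, test, registry)
        preds = pd.DataFrame(
            {
                "start_s": test["start_s"].to_numpy(),
                "actual": test["label"].to_numpy(dtype=object),
                "predicted": predicted,
            }
        )
        out[held_out] = (model, preds)
    return out
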