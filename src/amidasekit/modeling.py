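"""Consensus gradient-boosted-tree modelling of enzyme-substrate activity.

The workflow fits ten XGBoost classifiers, each on its own stratified
80/20 resample of the pair table (seeds 1..10, shared hyperparameters),
records which features attain nonzero gain importance in each model, and
keeps the features present in at least 70 % of the models.  A final
model restricted to that consensus set is trained on a separate fixed
stratified split and its gain importances are scaled to a maximum of 1.
Generalization is probed by grouped leave-one-out validation: one fold
per substrate (leave-one-chemical-out) or per enzyme
(leave-one-enzyme-out), reporting positive-class F1 and balanced
accuracy per fold.

Single-class conventions (held-out groups are frequently single-class):
the recall of a class absent from the truth is 1 when no predictions of
that class are made and 0 otherwise, and F1 is 1 when truth and
predictions both contain no positives.

Default hyperparameters are modest for tables of a few hundred rows:
depth-4 trees, learning rate 0.1, 200 rounds, no subsampling, histogram
construction on one thread, and a minimum split loss reduction
(``gamma``) of 5.0.  The nonzero ``gamma`` prunes splits whose loss
reduction is negligible, which is what makes "nonzero gain importance"
an informative notion of feature presence: without it boosted trees
happily spend splits on noise and the cross-model consensus degenerates
into a large, unstable feature set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from xgboost import XGBClassifier

from .featurization import FeatureTable


class ModelingError(ValueError):
    """Raised on contract violations in the modelling stage."""


DEFAULT_HYPERPARAMS: dict = {
    "max_depth": 4,
    "learning_rate": 0.1,
    "n_estimators": 200,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "gamma": 5.0,
    "tree_method": "hist",
    "n_jobs": 1,
    "objective": "binary:logistic",
    "eval_metric": "logloss",
}


@dataclass
class SplitSpec:
    """A stratified train/test split request."""

    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ModelingError("train_fraction must lie strictly between 0 and 1")


@dataclass
class EnsembleResult:
    """Per-model and consensus importances of the ten-model ensemble."""

    importances: pd.DataFrame  # features x models, gain importance
    seeds: list[int]
    hyperparams: dict
    consensus_features: list[str] = field(default_factory=list)
    final_importances: pd.Series | None = None  # scaled to max 1
    final_metrics: dict | None = None


@dataclass
class ValidationReport:
    """Grouped leave-one-out results, one row per held-out group."""

    folds: pd.DataFrame  # columns: group, n_test, f1, balanced_accuracy
    group_by: str
    predictions: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def classification_metrics(truth, predictions) -> tuple[float, float]:
    """Positive-class F1 and balanced accuracy with explicit single-class
    conventions (see module docstring).

    Returns ``(f1, balanced_accuracy)``, both in [0, 1].
    """
    y = np.asarray(truth, dtype=int)
    p = np.asarray(predictions, dtype=int)
    if y.shape != p.shape:
        raise ModelingError(f"length mismatch: truth {y.shape} vs predictions {p.shape}")
    tp = int(np.sum((y == 1) & (p == 1)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    tn = int(np.sum((y == 0) & (p == 0)))

    if (tp + fn) == 0:  # no true positives exist
        sensitivity = 1.0 if (tp + fp) == 0 else 0.0
        f1 = 1.0 if (tp + fp) == 0 else 0.0
    else:
        sensitivity = tp / (tp + fn)
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        f1 = (
            2 * precision * sensitivity / (precision + sensitivity)
            if (precision + sensitivity) > 0
            else 0.0
        )
    if (tn + fp) == 0:  # no true negatives exist
        specificity = 1.0 if (tn + fn) == 0 else 0.0
    else:
        specificity = tn / (tn + fp)
    return float(f1), float((sensitivity + specificity) / 2.0)


# ---------------------------------------------------------------------------
# Splitting and training
# ---------------------------------------------------------------------------

def stratified_split(table: FeatureTable, spec: SplitSpec):
    """Deterministic stratified row partition.

    Returns ``(train_index, test_index)`` as pandas indexes.  Class
    proportions match the full table within one row per class (test size
    rounds up: half rows round away from the test set's complement).
    """
    labels = table.labels
    if labels.nunique() < 2:
        raise ModelingError("stratified split requires both classes present")
    train_idx, test_idx = train_test_split(
        np.arange(len(labels)),
        train_size=spec.train_fraction,
        stratify=labels.to_numpy(),
        random_state=spec.seed,
        shuffle=True,
    )
    return table.data.index[np.sort(train_idx)], table.data.index[np.sort(test_idx)]


def _fit_model(X: pd.DataFrame, y: np.ndarray, hyperparams: dict, seed: int) -> XGBClassifier:
    params = {**DEFAULT_HYPERPARAMS, **(hyperparams or {})}
    model = XGBClassifier(**params, random_state=seed)
    model.fit(X, y)
    return model


def _gain_importance(model: XGBClassifier, feature_names: list[str]) -> pd.Series:
    score = model.get_booster().get_score(importance_type="gain")
    return pd.Series({f: score.get(f, 0.0) for f in feature_names}, dtype=float)


def train_boosted_ensemble(
    table: FeatureTable,
    n_models: int = 10,
    seeds: list[int] | None = None,
    hyperparams: dict | None = None,
    train_fraction: float = 0.8,
) -> EnsembleResult:
    """Train the resampled ensemble and record gain importances.

    Each model sees its own stratified ``train_fraction`` resample
    (split seed = its entry in ``seeds``, default 1..n_models) with
    shared hyperparameters; fully deterministic given the seeds.
    """
    seeds = list(seeds) if seeds is not None else list(range(1, n_models + 1))
    if len(seeds) != n_models or len(set(seeds)) != n_models:
        raise ModelingError("need exactly n_models distinct seeds")
    cols = {}
    for k, seed in enumerate(seeds):
        try:
            train_idx, _ = stratified_split(table, SplitSpec(train_fraction, seed=seed))
            X = table.data.loc[train_idx]
            y = table.labels.loc[train_idx].to_numpy()
            model = _fit_model(X, y, hyperparams, seed)
        except Exception as err:
            raise ModelingError(f"training failed for ensemble model {k}: {err}") from err
        cols[f"model_{k}"] = _gain_importance(model, table.feature_names)
    importances = pd.DataFrame(cols)
    return EnsembleResult(
        importances=importances,
        seeds=seeds,
        hyperparams={**DEFAULT_HYPERPARAMS, **(hyperparams or {})},
    )


def consensus_feature_select(
    importances: pd.DataFrame, presence_threshold: float = 0.70
) -> list[str]:
    """Features with nonzero importance in at least
    ``ceil(threshold * n_models)`` of the models."""
    if importances.shape[1] == 0 or importances.shape[0] == 0:
        raise ModelingError("empty importance matrix")
    needed = math.ceil(presence_threshold * importances.shape[1])
    present = (importances > 0).sum(axis=1)
    return list(importances.index[present >= needed])


def train_final_model(
    table: FeatureTable,
    consensus_features: list[str],
    spec: SplitSpec | None = None,
    hyperparams: dict | None = None,
):
    """Fit the final model on the consensus features.

    Trains on a fixed stratified split (seed 0 by default, separate from
    the ten resamples), reports held-out accuracy/F1/balanced accuracy,
    and returns ``(model, scaled_importances, metrics)`` with
    importances divided by their maximum.
    """
    if not consensus_features:
        raise ModelingError(
            "consensus feature set is empty; review the presence threshold or ensemble size"
        )
    spec = spec or SplitSpec(seed=0)
    train_idx, test_idx = stratified_split(table, spec)
    X = table.data[consensus_features]
    y = table.labels
    model = _fit_model(X.loc[train_idx], y.loc[train_idx].to_numpy(), hyperparams, spec.seed)
    raw = _gain_importance(model, consensus_features)
    top = raw.max()
    scaled = raw / top if top > 0 else raw
    pred = model.predict(X.loc[test_idx])
    f1, ba = classification_metrics(y.loc[test_idx].to_numpy(), pred)
    metrics = {
        "accuracy": float(np.mean(pred == y.loc[test_idx].to_numpy())),
        "f1": f1,
        "balanced_accuracy": ba,
        "n_test": int(len(test_idx)),
    }
    return model, scaled.sort_values(ascending=False), metrics


def run_consensus_pipeline(
    table: FeatureTable,
    n_models: int = 10,
    presence_threshold: float = 0.70,
    hyperparams: dict | None = None,
    final_spec: SplitSpec | None = None,
) -> EnsembleResult:
    """Ensemble, consensus selection and final model in one call."""
    result = train_boosted_ensemble(table, n_models=n_models, hyperparams=hyperparams)
    result.consensus_features = consensus_feature_select(result.importances, presence_threshold)
    _, scaled, metrics = train_final_model(
        table, result.consensus_features, spec=final_spec, hyperparams=hyperparams
    )
    result.final_importances = scaled
    result.final_metrics = metrics
    return result


# ---------------------------------------------------------------------------
# Grouped validation
# ---------------------------------------------------------------------------

def leave_one_group_out(
    table: FeatureTable,
    group_by: str = "chemical",
    hyperparams: dict | None = None,
) -> ValidationReport:
    """Leave-one-chemical-out / leave-one-enzyme-out validation.

    One fold per group: the model trains on all other groups and is
    evaluated on the held-out group.  If the training labels collapse to
    a single class the fold predicts that class throughout (a constant
    model is the only fit).
    """
    level = {"chemical": "substrate_id", "enzyme": "enzyme_id"}.get(group_by)
    if level is None:
        raise ModelingError(f"group_by must be 'chemical' or 'enzyme', got {group_by!r}")
    if level not in table.data.index.names:
        raise ModelingError(f"feature table index lacks the {level!r} level")
    groups = table.data.index.get_level_values(level)
    unique_groups = sorted(pd.unique(groups))
    if len(unique_groups) < 2:
        raise ModelingError("grouped validation needs at least two groups")
    rows = []
    predictions = {}
    for group in unique_groups:
        test_mask = groups == group
        X_train, y_train = table.data[~test_mask], table.labels[~test_mask].to_numpy()
        X_test, y_test = table.data[test_mask], table.labels[test_mask].to_numpy()
        if len(np.unique(y_train)) < 2:
            pred = np.full(len(y_test), int(y_train[0]))
        else:
            model = _fit_model(X_train, y_train, hyperparams, seed=0)
            pred = model.predict(X_test).astype(int)
        f1, ba = classification_metrics(y_test, pred)
        rows.append(
            {"group": group, "n_test": int(test_mask.sum()), "f1": f1, "balanced_accuracy": ba}
        )
        predictions[group] = pred
    return ValidationReport(
        folds=pd.DataFrame(rows), group_by=group_by, predictions=predictions
    )
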