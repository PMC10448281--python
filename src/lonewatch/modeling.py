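"""Classifier evaluation under leave-one-participant-out cross-validation.

Two models — a Gini decision tree and gradient boosting — are evaluated
per feature dataset. Inside every fold, recursive feature elimination
removes the least-important physical-activity feature one round at a
time until a target count remains (non-activity columns are never
eliminated), then the model is fitted on the fold's training partition
only. Out-of-fold predictions are pooled before metrics are computed;
per-fold macro averages are also reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score
from sklearn.tree import DecisionTreeClassifier, export_graphviz

from lonewatch.datasets import FeatureDataset, activity_columns
from lonewatch.errors import MetricError, ParameterError

DEFAULT_RFE_K = 10

MODEL_KINDS = ("decision_tree", "gradient_boosting")
_KIND_ALIASES = {"dt": "decision_tree", "gb": "gradient_boosting"}


@dataclass
class ModelSpec:
    """Classifier kind plus hyperparameters; the tree always splits on Gini."""

    kind: str = "decision_tree"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.kind = _KIND_ALIASES.get(self.kind, self.kind)
        if self.kind not in MODEL_KINDS:
            raise ParameterError(f"unknown model kind {self.kind!r}")

    def build(self):
        if self.kind == "decision_tree":
            params = {"max_depth": 4, "min_samples_leaf": 2}
            params.update(self.hyperparameters)
            return DecisionTreeClassifier(
                criterion="gini", random_state=self.seed, **params
            )
        params = {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3}
        params.update(self.hyperparameters)
        return GradientBoostingClassifier(random_state=self.seed, **params)


@dataclass
class EvaluationReport:
    """Metrics, per-fold predictions and importances for one (dataset, model)."""

    dataset_name: str
    model_kind: str
    metrics: dict
    fold_metrics: dict
    y_true: np.ndarray
    y_pred: np.ndarray
    y_score: np.ndarray
    fold_participants: list[str]
    skipped_folds: list[str]
    importances: pd.Series
    selected_features: list[str]
    tree_dot: Optional[str] = None


def rfe_select(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: ModelSpec,
    k: int,
    activity_cols: Sequence[str],
) -> list[str]:
    """Columns surviving RFE over the activity features.

    One least-important activity feature is removed per round (refit each
    round) until ``k`` activity features remain. Non-activity columns are
    always kept. ``k`` at or above the activity count is the identity
    (with a warning).
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    cols = list(X.columns)
    act = [c for c in cols if c in set(activity_cols)]
    if not act:
        return cols
    if k >= len(act):
        if k > len(act):
            warnings.warn(
                f"rfe_k={k} >= {len(act)} activity features; nothing to eliminate",
                stacklevel=2,
            )
        return cols
    while len(act) > k:
        est = spec.build()
        est.fit(X[cols], y)
        imp = pd.Series(est.feature_importances_, index=cols)
        worst = imp.loc[act].idxmin()
        act.remove(worst)
        cols.remove(worst)
    return cols


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, y_score: Optional[np.ndarray] = None
) -> dict:
    """Per-class precision/recall/F1, weighted F1, sensitivity, specificity, AUC.

    Class 1 is the loneliness class: sensitivity is its recall,
    specificity the recall of class 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise MetricError("length mismatch")
    if len(np.unique(y_true)) < 2:
        raise MetricError("both classes must be present in y_true")
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=[0, 1], zero_division=0
    )
    weighted_f1 = float(np.average(f1, weights=support))
    out = {
        "precision_0": float(prec[0]),
        "recall_0": float(rec[0]),
        "f1_0": float(f1[0]),
        "precision_1": float(prec[1]),
        "recall_1": float(rec[1]),
        "f1_1": float(f1[1]),
        "weighted_f1": weighted_f1,
        "sensitivity": float(rec[1]),
        "specificity": float(rec[0]),
    }
    if y_score is not None:
        out["auc"] = float(roc_auc_score(y_true, y_score))
    return out


def lopo_evaluate(
    dataset: FeatureDataset,
    spec: ModelSpec,
    rfe_k: Optional[int] = DEFAULT_RFE_K,
    export_tree: bool = False,
    rfe_spec: Optional[ModelSpec] = None,
) -> EvaluationReport:
    """Leave-one-participant-out evaluation of one model on one dataset.

    All samples of a participant are held out together; RFE and model
    fitting happen strictly inside each fold's training partition
    (``rfe_spec`` may supply a cheaper estimator for the elimination
    ranking; the fold model always uses ``spec``). Folds
    whose training partition contains a single class are skipped and
    recorded. Metrics are computed on pooled out-of-fold predictions.
    """
    X, y, groups = dataset.X, dataset.y, dataset.participants
    participants = list(pd.unique(groups))
    if len(participants) < 2:
        raise ParameterError("need at least 2 participants")
    act_cols = activity_columns(dataset)

    y_true_parts, y_pred_parts, y_score_parts = [], [], []
    fold_participants, skipped = [], []
    fold_metric_rows = []
    importance_rows = []
    selected_last: list[str] = list(X.columns)
    last_tree_est = None

    for pid in participants:
        test_mask = groups == pid
        X_tr, y_tr = X.loc[~test_mask], y[~test_mask]
        X_te, y_te = X.loc[test_mask], y[test_mask]
        if len(np.unique(y_tr)) < 2:
            skipped.append(str(pid))
            warnings.warn(f"fold {pid}: one-class training partition, skipped",
                          stacklevel=2)
            continue
        if rfe_k is not None and act_cols:
            cols = rfe_select(X_tr, y_tr, rfe_spec or spec, rfe_k, act_cols)
        else:
            cols = list(X.columns)
        est = spec.build()
        est.fit(X_tr[cols], y_tr)
        pred = est.predict(X_te[cols])
        score = est.predict_proba(X_te[cols])[:, list(est.classes_).index(1)]
        y_true_parts.append(y_te)
        y_pred_parts.append(pred)
        y_score_parts.append(score)
        fold_participants.extend([str(pid)] * len(y_te))
        importance_rows.append(
            pd.Series(est.feature_importances_, index=cols)
        )
        fold_metric_rows.append(
            {"accuracy": float(np.mean(pred == y_te))}
        )
        selected_last = cols
        if spec.kind == "decision_tree":
            last_tree_est = (est, cols)

    if not y_true_parts:
        raise MetricError("all folds skipped")
    y_true = np.concatenate(y_true_parts)
    y_pred = np.concatenate(y_pred_parts)
    y_score = np.concatenate(y_score_parts)
    try:
        metrics = compute_metrics(y_true, y_pred, y_score)
    except MetricError:
        # skipped folds can leave a one-class pooled truth
        warnings.warn("pooled out-of-fold truth has one class; metrics undefined",
                      stacklevel=2)
        metrics = {}

    fold_metrics = {
        "accuracy_mean": float(np.mean([m["accuracy"] for m in fold_metric_rows])),
        "n_folds": len(fold_metric_rows),
    }
    importances = (
        pd.concat(importance_rows, axis=1)
        .fillna(0.0)
        .mean(axis=1)
        .sort_values(ascending=False)
    )

    tree_dot = None
    if export_tree and last_tree_est is not None:
        est, cols = last_tree_est
        tree_dot = export_graphviz(
            est, feature_names=cols, class_names=["nonlonely", "loneliness"],
            filled=False,
        )

    return EvaluationReport(
        dataset_name=dataset.name,
        model_kind=spec.kind,
        metrics=metrics,
        fold_metrics=fold_metrics,
        y_true=y_true,
        y_pred=y_pred,
        y_score=y_score,
        fold_participants=fold_participants,
        skipped_folds=skipped,
        importances=importances,
        selected_features=list(selected_last),
        tree_dot=tree_dot,
    )


def feature_importance(report: EvaluationReport) -> pd.DataFrame:
    """Ranked mean impurity importances across folds."""
    return (
        report.importances.rename("mean_importance")
        .rename_axis("feature")
        .reset_index()
    )


def metrics_table(reports: Sequence[EvaluationReport]) -> pd.DataFrame:
    """One row per (dataset, model) with the ten headline measures."""
    cols = [
        "precision_0", "recall_0", "f1_0",
        "precision_1", "recall_1", "f1_1",
        "weighted_f1", "sensitivity", "specificity", "auc",
    ]
    rows = []
    for r in reports:
        row = {"dataset": r.dataset_name, "model": r.model_kind}
        row.update({c: r.metrics.get(c, np.nan) for c in cols})
        rows.append(row)
    return pd.DataFrame(rows)
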