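"""RFE, LOPO evaluation, metric identities, feature importances."""

import numpy as np
import pandas as pd
import pytest

from lonewatch.datasets import FeatureDataset
from lonewatch.errors import MetricError, ParameterError
from lonewatch.modeling import (
    ModelSpec,
    compute_metrics,
    feature_importance,
    lopo_evaluate,
    metrics_table,
    rfe_select,
)


def _dataset(X, y, participants, name="pa", activity_cols=None):
    return FeatureDataset(
        name=name,
        X=X,
        y=np.asarray(y, dtype=int),
        participants=np.asarray(participants),
        feature_names=tuple(X.columns),
    )


def _separable(n_participants=12, samples_per=2, seed=0):
    """Perfectly separable dataset keyed on one activity feature."""
    rng = np.random.default_rng(seed)
    rows, y, pids = [], [], []
    for i in range(n_participants):
        lab = i % 2
        for _ in range(samples_per):
            rows.append(
                {
                    "activity_intensity": (5.0 if lab else 10.0)
                    + rng.normal(0, 0.1),
                    "steps_mean": rng.normal(0, 1),
                    "tst": rng.normal(450, 20),
                }
            )
            y.append(lab)
            pids.append(f"p{i}")
    return _dataset(pd.DataFrame(rows), y, pids)


class TestModelSpec:
    def test_aliases(self):
        assert ModelSpec("dt").kind == "decision_tree"
        assert ModelSpec("gb").kind == "gradient_boosting"

    def test_unknown_rejected(self):
        with pytest.raises(ParameterError):
            ModelSpec("random_forest")

    def test_tree_uses_gini(self):
        est = ModelSpec("dt").build()
        assert est.criterion == "gini"


class TestRFE:
    def test_identity_when_k_covers_all(self):
        d = _separable()
        cols = rfe_select(
            d.X, d.y, ModelSpec("dt"), k=2,
            activity_cols=["activity_intensity", "steps_mean"],
        )
        assert cols == list(d.X.columns)

    def test_noise_eliminated_before_signal(self):
        rng = np.random.default_rng(3)
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(
            {
                "noise_col": rng.normal(0, 1, n),
                "signal_col": y * 5.0 + rng.normal(0, 0.1, n),
            }
        )
        cols = rfe_select(
            X, y, ModelSpec("dt"), k=1, activity_cols=["noise_col", "signal_col"]
        )
        assert cols == ["signal_col"]

    def test_non_activity_never_eliminated(self):
        d = _separable()
        cols = rfe_select(
            d.X, d.y, ModelSpec("dt"), k=1,
            activity_cols=["activity_intensity", "steps_mean"],
        )
        assert "tst" in cols
        assert len([c for c in cols if c != "tst"]) == 1

    def test_no_activity_columns_identity(self):
        d = _separable()
        cols = rfe_select(d.X, d.y, ModelSpec("dt"), k=1, activity_cols=[])
        assert cols == list(d.X.columns)

    def test_k_above_count_warns(self):
        d = _separable()
        with pytest.warns(UserWarning):
            cols = rfe_select(
                d.X, d.y, ModelSpec("dt"), k=5,
                activity_cols=["activity_intensity", "steps_mean"],
            )
        assert cols == list(d.X.columns)


class TestComputeMetrics:
    def test_confusion_example(self):
        # TP=15 FN=2 TN=19 FP=3
        y_true = [1] * 17 + [0] * 22
        y_pred = [1] * 15 + [0] * 2 + [0] * 19 + [1] * 3
        m = compute_metrics(y_true, y_pred)
        assert m["sensitivity"] == pytest.approx(15 / 17)
        assert m["specificity"] == pytest.approx(19 / 22)
        assert m["precision_1"] == pytest.approx(15 / 18)
        assert m["recall_1"] == pytest.approx(15 / 17)
        assert m["precision_0"] == pytest.approx(19 / 21)
        f1_1 = 2 * (15 / 18) * (15 / 17) / ((15 / 18) + (15 / 17))
        f1_0 = 2 * (19 / 21) * (19 / 22) / ((19 / 21) + (19 / 22))
        expected_weighted = (17 * f1_1 + 22 * f1_0) / 39
        assert m["weighted_f1"] == pytest.approx(expected_weighted, rel=1e-9)

    def test_perfect_predictions(self):
        y = [0, 1, 0, 1, 1]
        m = compute_metrics(y, y, y_score=y)
        for k in ("weighted_f1", "sensitivity", "specificity", "auc"):
            assert m[k] == 1.0

    def test_all_positive_degenerate(self):
        m = compute_metrics([0, 1, 0, 1], [1, 1, 1, 1])
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.0

    def test_one_class_truth_rejected(self):
        with pytest.raises(MetricError):
            compute_metrics([1, 1, 1], [1, 0, 1])

    def test_identity_recalls(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 50)
        y_true[:2] = [0, 1]
        y_pred = rng.integers(0, 2, 50)
        m = compute_metrics(y_true, y_pred)
        assert m["sensitivity"] == m["recall_1"]
        assert m["specificity"] == m["recall_0"]


class TestLOPO:
    def test_fold_structure_31_participants_39_samples(self):
        rng = np.random.default_rng(7)
        rows, y, pids = [], [], []
        for i in range(31):
            lab = int(i < 13)
            n_samples = 2 if i < 8 else 1
            for _ in range(n_samples):
                rows.append({"f1": lab * 3 + rng.normal(), "f2": rng.normal()})
                y.append(lab)
                pids.append(f"p{i:02d}")
        d = _dataset(pd.DataFrame(rows), y, pids, name="hrv")
        report = lopo_evaluate(d, ModelSpec("dt"), rfe_k=None)
        assert report.fold_metrics["n_folds"] == 31
        assert len(report.y_true) == 39
        # each participant's samples pooled exactly once
        counts = pd.Series(report.fold_participants).value_counts()
        assert counts.loc[[f"p{i:02d}" for i in range(8)]].eq(2).all()
        assert counts.sum() == 39

    def test_separable_perfect_f1(self):
        report = lopo_evaluate(_separable(), ModelSpec("dt"), rfe_k=None)
        assert report.metrics["weighted_f1"] == 1.0

    def test_fold_disjointness(self):
        d = _separable(n_participants=8)
        report = lopo_evaluate(d, ModelSpec("dt"), rfe_k=None)
        assert sorted(report.fold_participants) == sorted(d.participants)

    def test_metric_identity_from_pooled_confusion(self):
        d = _separable(n_participants=10, seed=5)
        report = lopo_evaluate(d, ModelSpec("dt"), rfe_k=None)
        recomputed = compute_metrics(report.y_true, report.y_pred)
        assert report.metrics["weighted_f1"] == pytest.approx(
            recomputed["weighted_f1"], abs=1e-12
        )

    def test_single_participant_rejected(self):
        d = _separable(n_participants=1)
        with pytest.raises(ParameterError):
            lopo_evaluate(d, ModelSpec("dt"))

    def test_one_class_training_fold_skipped(self):
        # all class-0 samples sit in one participant, so that fold's
        # training partition is one-class and the pooled truth degenerates
        X = pd.DataFrame({"f": [0.0, 1.0, 2.0, 3.0]})
        d = _dataset(X, [0, 1, 1, 1], ["a", "b", "c", "d"], name="hrv")
        with pytest.warns(UserWarning):
            report = lopo_evaluate(d, ModelSpec("dt"), rfe_k=None)
        assert report.skipped_folds == ["a"]
        assert report.metrics == {}

    def test_permutation_null_auc(self):
        # shuffled labels: mean AUC near chance (quick version; the full
        # 50-shuffle check lives in the acceptance suite)
        rng = np.random.default_rng(11)
        aucs = []
        for _ in range(15):
            d = _separable(n_participants=10, seed=rng.integers(1 << 31))
            y = d.y.copy()
            rng.shuffle(y)
            if len(np.unique(y)) < 2 or min(np.bincount(y)) < 3:
                continue
            d.y = y
            try:
                report = lopo_evaluate(d, ModelSpec("dt"), rfe_k=None)
            except MetricError:
                continue
            aucs.append(report.metrics["auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.15


class TestFeatureImportance:
    def test_single_informative_ranks_first(self):
        rng = np.random.default_rng(2)
        n = 80
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(
            {f"noise_{i}": rng.normal(0, 1, n) for i in range(5)}
        )
        X["informative"] = y * 4 + rng.normal(0, 0.2, n)
        d = _dataset(X, y, [f"p{i % 16}" for i in range(n)], name="hrv")
        report = lopo_evaluate(d, ModelSpec("dt"), rfe_k=None)
        assert report.importances.index[0] == "informative"

    def test_all_noise_no_dominant_feature(self):
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 40
            y = np.repeat([0, 1], n // 2)
            X = pd.DataFrame({f"n{i}": rng.normal(0, 1, n) for i in range(6)})
            d = _dataset(X, y, [f"p{i % 10}" for i in range(n)], name="hrv")
            report = lopo_evaluate(d, ModelSpec("dt", seed=seed), rfe_k=None)
            means.append(report.importances)
        mean_imp = pd.concat(means, axis=1).fillna(0.0).mean(axis=1)
        assert mean_imp.max() <= 3.0 / 6.0

    def test_importance_table_shape(self):
        report = lopo_evaluate(_separable(), ModelSpec("dt"), rfe_k=None)
        table = feature_importance(report)
        assert list(table.columns) == ["feature", "mean_importance"]
        assert table["mean_importance"].is_monotonic_decreasing

    def test_tree_dot_exported(self):
        report = lopo_evaluate(
            _separable(), ModelSpec("dt"), rfe_k=None, export_tree=True
        )
        assert report.tree_dot is not None
        assert "digraph" in report.tree_dot


class TestMetricsTable:
    def test_table_columns(self):
        reports = [lopo_evaluate(_separable(), ModelSpec(k), rfe_k=None)
                   for k in ("dt", "gb")]
        table = metrics_table(reports)
        assert len(table) == 2
        assert {"weighted_f1", "sensitivity", "specificity", "auc"} <= set(
            table.columns
        )
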