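"""Label clustering, SMOTE, training, LOSO evaluation, selection, export."""

import numpy as np
import pandas as pd
import pytest

from vocalics import models
from vocalics.models import (
    EvaluationReport,
    FoldResult,
    SignalTarget,
    build_training_set,
    cluster_labels,
    export_decision_paths,
    loso_evaluate,
    predict_slices,
    select_model,
    smote_resample,
    train_signal_model,
)

TARGET = SignalTarget("dominance", "provider")


@pytest.mark.parametrize(
    "raw,expected",
    [(1, "low"), (2, "low"), (3, "neutral"), (4, "high"), (5, "high"), (6, "high")],
)
def test_cluster_labels(raw, expected):
    assert cluster_labels(raw) == expected


@pytest.mark.parametrize("raw", [0, 7, -1])
def test_cluster_labels_out_of_range(raw):
    with pytest.raises(ValueError):
        cluster_labels(raw)


def _toy_frame(raws, n_features=4, seed=0, separable_by=None):
    """Features + labels tables; optionally make column 0 separate the classes."""
    rng = np.random.default_rng(seed)
    n = len(raws)
    X = rng.normal(size=(n, n_features))
    if separable_by is not None:
        classes = np.array([cluster_labels(r) for r in raws])
        X[:, 0] = np.where(classes == "high", 5.0, -5.0) + rng.normal(0, 0.1, n)
    feats = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    feats.insert(0, "visit_id", [f"v{i // 3}" for i in range(n)])
    feats.insert(1, "slice_index", [i % 3 for i in range(n)])
    feats.insert(2, "provider_id", [f"p{i % 5}" for i in range(n)])
    labels = feats[["visit_id", "slice_index"]].copy()
    labels[TARGET.column] = raws
    return feats, labels


class TestBuildTrainingSet:
    def test_low_rows_discarded(self):
        feats, labels = _toy_frame([3, 2, 5])
        ds = build_training_set(feats, labels, TARGET)
        assert len(ds.y) == 2
        assert set(ds.y) == {"neutral", "high"}

    def test_no_low_keeps_all(self):
        feats, labels = _toy_frame([3, 4, 5, 3])
        assert len(build_training_set(feats, labels, TARGET).y) == 4

    def test_counting_oracle(self):
        rng = np.random.default_rng(2)
        raws = rng.choice([1, 2, 3, 4, 5, 6], size=60, p=[.02, .03, .45, .2, .2, .1])
        feats, labels = _toy_frame(list(raws))
        ds = build_training_set(feats, labels, TARGET)
        assert len(ds.y) == len(raws) - int(np.isin(raws, [1, 2]).sum())

    def test_single_class_error(self):
        feats, labels = _toy_frame([3, 3, 3, 2])
        with pytest.raises(ValueError, match="training impossible|only"):
            build_training_set(feats, labels, TARGET)


class TestSMOTE:
    def test_balances_counts(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 6))
        y = np.array(["high"] * 10 + ["neutral"] * 40)
        Xb, yb = smote_resample(X, y, rng)
        values, counts = np.unique(yb, return_counts=True)
        assert dict(zip(values, counts)) == {"high": 40, "neutral": 40}

    def test_synthetic_points_in_minority_hull(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.uniform(10, 11, (5, 2)), rng.uniform(0, 1, (20, 2))])
        y = np.array(["high"] * 5 + ["neutral"] * 20)
        Xb, yb = smote_resample(X, y, rng)
        new = Xb[len(X):]
        assert np.all(new >= 10) and np.all(new <= 11)

    def test_singleton_minority_duplicated(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        y = np.array(["high"] + ["neutral"] * 4)
        Xb, yb = smote_resample(X, y, rng)
        assert (yb == "high").sum() == 4
        assert np.allclose(Xb[5:], X[0])


def _separable_dataset(n=40, n_providers=5, seed=0):
    rng = np.random.default_rng(seed)
    raws = [3 if i % 2 else 5 for i in range(n)]
    feats, labels = _toy_frame(raws, seed=seed, separable_by=0)
    feats["provider_id"] = [f"p{i % n_providers}" for i in range(n)]
    return build_training_set(feats, labels, TARGET)


class TestTraining:
    @pytest.mark.parametrize("family", ["LR", "DTC", "SVM-linear", "RF"])
    def test_separable_training_f1(self, family):
        ds = _separable_dataset()
        model = train_signal_model(ds, family, TARGET, seed=1)
        from sklearn.metrics import f1_score

        pred = model.predict(ds.X)
        assert f1_score(ds.y, pred, average="macro", labels=["neutral", "high"]) == 1.0

    def test_same_seed_identical(self):
        ds = _separable_dataset()
        m1 = train_signal_model(ds, "LR", TARGET, seed=7)
        m2 = train_signal_model(ds, "LR", TARGET, seed=7)
        assert np.array_equal(m1.predict(ds.X), m2.predict(ds.X))
        assert np.array_equal(m1.estimator.coef_, m2.estimator.coef_)
        assert m1.best_params == m2.best_params


class TestLOSO:
    def test_fold_structure(self):
        ds = _separable_dataset(n=40, n_providers=5)
        report = loso_evaluate(ds, "DTC", TARGET, seed=0)
        assert len(report.folds) == 5
        assert sorted(f.provider for f in report.folds) == [f"p{i}" for i in range(5)]
        assert sum(f.n_test for f in report.folds) == 40

    def test_chance_level_on_noise(self):
        """Labels independent of features: mean macro-F1 near one half."""
        rng = np.random.default_rng(0)
        n = 180
        raws = list(rng.choice([3, 5], size=n))
        feats, labels = _toy_frame(raws, n_features=8, seed=3)
        feats["provider_id"] = [f"p{i % 6}" for i in range(n)]
        ds = build_training_set(feats, labels, TARGET)
        report = loso_evaluate(ds, "LR", TARGET, grid={"C": [1.0]}, seed=0)
        assert 0.3 <= report.mean_macro_f1 <= 0.7

    def test_single_class_fold_skipped(self):
        feats, labels = _toy_frame([3, 3, 5, 5, 3, 3], seed=1)
        feats["provider_id"] = ["p0", "p0", "p1", "p1", "p2", "p2"]
        ds = build_training_set(feats, labels, TARGET)
        report = loso_evaluate(ds, "DTC", TARGET, grid={"max_depth": [2]}, seed=0)
        # p1 holds every above-baseline row, so its fold cannot be trained
        assert report.skipped_providers == ["p1"]
        assert sorted(f.provider for f in report.folds) == ["p0", "p2"]


def _report(family, f1):
    return EvaluationReport(
        target=TARGET, family=family,
        folds=[FoldResult(provider="p0", n_test=1, accuracy=f1, macro_f1=f1)],
    )


class TestSelection:
    def test_argmax(self):
        assert select_model([_report("LR", 0.66), _report("DTC", 0.74)]) == "DTC"

    def test_tie_prefers_interpretable(self):
        assert select_model([_report("RF", 0.7), _report("LR", 0.7)]) == "LR"
        assert select_model([_report("LR", 0.7), _report("DTC", 0.7)]) == "DTC"

    def test_order_invariance(self):
        reports = [_report("RF", 0.61), _report("GBDT", 0.66), _report("LR", 0.64)]
        import itertools

        choices = {
            select_model(perm) for perm in itertools.permutations(reports)
        }
        assert choices == {"GBDT"}


class TestPrediction:
    def test_schema_mismatch(self):
        ds = _separable_dataset()
        model = train_signal_model(ds, "DTC", TARGET, grid={"max_depth": [2]}, seed=0)
        feats = pd.DataFrame(np.zeros((2, 3)), columns=["f0", "f1", "f2"])
        with pytest.raises(models.SchemaError, match="f3"):
            predict_slices(model, feats)

    def test_column_realignment(self):
        ds = _separable_dataset()
        model = train_signal_model(ds, "LR", TARGET, grid={"C": [1.0]}, seed=0)
        feats = pd.DataFrame(ds.X, columns=ds.feature_names)
        shuffled = feats[list(reversed(feats.columns))]
        assert predict_slices(model, feats).equals(predict_slices(model, shuffled))

    def test_zero_row_is_valid_input(self):
        ds = _separable_dataset()
        model = train_signal_model(ds, "LR", TARGET, grid={"C": [1.0]}, seed=0)
        feats = pd.DataFrame(np.zeros((1, len(ds.feature_names))),
                             columns=ds.feature_names)
        assert predict_slices(model, feats).iloc[0] in ("neutral", "high")


class TestInterpretability:
    def test_depth_one_tree_names_root_feature(self):
        ds = _separable_dataset()
        model = train_signal_model(ds, "DTC", TARGET, grid={"max_depth": [1]}, seed=0)
        export = export_decision_paths(model)
        assert export["interpretability"] == "global"
        assert export["ranked_features"][0]["feature"] == "f0"
        assert "f0" in export["tree_text"]

    def test_lr_dominant_coefficient_ranked_first(self):
        ds = _separable_dataset()
        model = train_signal_model(ds, "LR", TARGET, grid={"C": [1.0]}, seed=0)
        export = export_decision_paths(model)
        assert export["ranked_features"][0]["feature"] == "f0"

    def test_ensemble_tagged_local(self):
        ds = _separable_dataset()
        model = train_signal_model(
            ds, "RF", TARGET, grid={"n_estimators": [30], "max_depth": [3]}, seed=0
        )
        export = export_decision_paths(model)
        assert export["interpretability"] == "local"
        assert export["ranked_features"][0]["feature"] == "f0"


def test_no_leakage_fold_fit_ignores_heldout_labels():
    """Corrupting the held-out provider's labels leaves that fold's model
    predictions identical."""
    ds = _separable_dataset(n=40, n_providers=4, seed=5)
    held = "p0"
    mask = ds.groups == held

    def fold_model(dataset):
        train = models.Dataset(
            X=dataset.X[~mask], y=dataset.y[~mask], groups=dataset.groups[~mask],
            feature_names=dataset.feature_names,
            keys=dataset.keys[~mask].reset_index(drop=True),
        )
        return train_signal_model(train, "LR", TARGET, grid={"C": [1.0]}, seed=3)

    corrupted = models.Dataset(
        X=ds.X, y=ds.y.copy(), groups=ds.groups,
        feature_names=ds.feature_names, keys=ds.keys,
    )
    corrupted.y[mask] = np.where(ds.y[mask] == "high", "neutral", "high")
    m1, m2 = fold_model(ds), fold_model(corrupted)
    assert np.array_equal(m1.estimator.coef_, m2.estimator.coef_)
    assert np.array_equal(m1.predict(ds.X[mask]), m2.predict(ds.X[mask]))
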