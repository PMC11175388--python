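"""Social-signal classifiers: label clustering, SMOTE-balanced training,
leave-one-provider-out evaluation, model selection and interpretability.

Eight targets are modelled (dominance, interactiveness, engagement, warmth ×
provider/patient). Raw 1–6 affect ratings are clustered into below-baseline
(1–2), baseline (3) and above-baseline (4–6); below-baseline slices are too
rare to model and are discarded, so each classifier separates *neutral* from
*high*. Training folds are balanced with SMOTE; hyperparameters are chosen by
an inner stratified 3-fold grid search on macro-F1; evaluation leaves one
provider out per fold so no provider appears on both sides of a split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier, export_text

log = logging.getLogger(__name__)

SIGNALS = ("dominance", "interactiveness", "engagement", "warmth")
MODEL_ROLES = ("provider", "patient")

NEUTRAL, HIGH = "neutral", "high"
CLASSES = (NEUTRAL, HIGH)

FAMILIES = ("LR", "DTC", "SVM-linear", "SVM-RBF", "RF", "GBDT")
#: globally interpretable families, in tie-break preference order
INTERPRETABLE_FAMILIES = ("DTC", "LR", "SVM-linear")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "LR": {"C": [0.01, 0.1, 1.0, 10.0]},
    "DTC": {"max_depth": [3, 5, 8, None]},
    "SVM-linear": {"C": [0.1, 1.0, 10.0]},
    "SVM-RBF": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.1]},
    "RF": {"n_estimators": [100, 300], "max_depth": [3, 8]},
    "GBDT": {"n_estimators": [100, 300], "max_depth": [3, 8]},
}
#: families whose inputs are z-scored (trees are scale-invariant)
SCALED_FAMILIES = frozenset({"LR", "SVM-linear", "SVM-RBF"})


class SchemaError(ValueError):
    """Feature columns do not match what a model was fit on."""


class SignalTarget(NamedTuple):
    signal: str
    role: str

    @property
    def column(self) -> str:
        return f"{self.role}_{self.signal}"


ALL_TARGETS = tuple(
    SignalTarget(signal, role) for signal in SIGNALS for role in MODEL_ROLES
)
LABEL_COLUMNS = [t.column for t in ALL_TARGETS]


def cluster_labels(raw: int) -> str:
    """Cluster a raw 1–6 affect rating: 1–2 low, 3 neutral, 4–6 high."""
    if raw in (1, 2):
        return "low"
    if raw == 3:
        return NEUTRAL
    if raw in (4, 5, 6):
        return HIGH
    raise ValueError(f"raw affect rating must be in 1..6, got {raw!r}")


@dataclass
class Dataset:
    """Feature matrix with binary classes and provider grouping for LOSO."""

    X: np.ndarray
    y: np.ndarray  # strings in CLASSES
    groups: np.ndarray  # provider ids
    feature_names: list[str]
    keys: pd.DataFrame  # visit_id, slice_index


def build_training_set(
    features: pd.DataFrame, labels: pd.DataFrame, target: SignalTarget
) -> Dataset:
    """Join features to one target's labels and drop below-baseline rows.

    ``features`` must carry visit_id, slice_index, provider_id plus the
    feature columns; ``labels`` carries visit_id, slice_index and the raw
    1–6 score column for each target.
    """
    merged = features.merge(
        labels[["visit_id", "slice_index", target.column]],
        on=["visit_id", "slice_index"],
        validate="one_to_one",
    )
    classes = merged[target.column].astype(int).map(cluster_labels)
    keep = classes != "low"
    merged, classes = merged[keep], classes[keep]
    if classes.nunique() < 2:
        raise ValueError(
            f"target {target.column}: only {sorted(classes.unique())} present "
            "after discarding below-baseline rows; training impossible"
        )
    feature_names = [
        c
        for c in features.columns
        if c not in ("visit_id", "slice_index", "provider_id")
    ]
    return Dataset(
        X=merged[feature_names].to_numpy(dtype=float),
        y=classes.to_numpy(),
        groups=merged["provider_id"].to_numpy(),
        feature_names=feature_names,
        keys=merged[["visit_id", "slice_index"]].reset_index(drop=True),
    )


def smote_resample(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Balance a binary training set by synthetic minority oversampling.

    New minority points are drawn on segments between a minority sample and
    one of its k nearest minority neighbours, k = min(5, minority − 1). A
    singleton minority class is duplicated instead (interpolation is
    undefined), with a warning.
    """
    values, counts = np.unique(y, return_counts=True)
    if len(values) != 2 or counts.min() == counts.max():
        return X, y
    minority = values[np.argmin(counts)]
    n_needed = counts.max() - counts.min()
    X_min = X[y == minority]
    if len(X_min) == 1:
        log.warning("singleton minority class; duplicating instead of SMOTE")
        synth = np.repeat(X_min, n_needed, axis=0)
    else:
        k = min(5, len(X_min) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
        _, idx = nn.kneighbors(X_min)
        base = rng.integers(0, len(X_min), size=n_needed)
        pick = idx[base, rng.integers(1, k + 1, size=n_needed)]
        lam = rng.random(n_needed)[:, None]
        synth = X_min[base] + lam * (X_min[pick] - X_min[base])
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


def _make_estimator(family: str, params: Mapping[str, object], seed: int):
    if family == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    if family == "DTC":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "SVM-linear":
        return SVC(kernel="linear", random_state=seed, **params)
    if family == "SVM-RBF":
        return SVC(kernel="rbf", random_state=seed, **params)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if family == "GBDT":
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown model family {family!r}; expected one of {FAMILIES}")


def _grid_points(grid: Mapping[str, Sequence]) -> list[dict]:
    points = [{}]
    for key, values in grid.items():
        points = [{**p, key: v} for p in points for v in values]
    return points


@dataclass
class TrainedSignalModel:
    target: SignalTarget
    family: str
    estimator: object
    scaler: StandardScaler | None
    feature_names: list[str]
    best_params: dict
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(X) if self.scaler is not None else X
        return self.estimator.predict(Z)

    def sidecar(self) -> dict:
        """JSON-serializable provenance record for the model artifact."""
        return {
            "target": self.target.column,
            "family": self.family,
            "hyperparameters": {
                k: (v if v is None or isinstance(v, (int, float, str)) else str(v))
                for k, v in self.best_params.items()
            },
            "seed": self.seed,
            "feature_order": self.feature_names,
        }


def _fit_once(
    family: str,
    params: Mapping[str, object],
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    rng: np.random.Generator,
) -> tuple[object, StandardScaler | None]:
    scaler = None
    Z = X
    if family in SCALED_FAMILIES:
        scaler = StandardScaler().fit(X)
        Z = scaler.transform(X)
    Zb, yb = smote_resample(Z, y, rng)
    est = _make_estimator(family, params, seed).fit(Zb, yb)
    return est, scaler


def train_signal_model(
    dataset: Dataset,
    family: str,
    target: SignalTarget,
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
    inner_folds: int = 3,
) -> TrainedSignalModel:
    """Fit one family on a training set with SMOTE balancing and an inner
    stratified k-fold grid search maximizing macro-F1.

    Scaling, SMOTE and the grid search all see only ``dataset`` — callers
    evaluating held-out data must pass the training portion only.
    """
    grid = dict(grid if grid is not None else DEFAULT_GRIDS[family])
    X, y = dataset.X, dataset.y
    points = _grid_points(grid)
    best_params = points[0]
    if len(points) > 1:
        n_splits = min(inner_folds, int(np.bincount(pd.factorize(y)[0]).min()))
        scores = []
        if n_splits >= 2:
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            splits = list(skf.split(X, y))
            for params in points:
                fold_scores = []
                for j, (tr, va) in enumerate(splits):
                    rng = np.random.default_rng([seed, j])
                    est, scaler = _fit_once(family, params, X[tr], y[tr], seed, rng)
                    Zv = scaler.transform(X[va]) if scaler is not None else X[va]
                    fold_scores.append(
                        f1_score(y[va], est.predict(Zv), average="macro",
                                 labels=list(CLASSES), zero_division=0)
                    )
                scores.append(float(np.mean(fold_scores)))
            best_params = points[int(np.argmax(scores))]
    rng = np.random.default_rng([seed, 997])
    est, scaler = _fit_once(family, best_params, X, y, seed, rng)
    return TrainedSignalModel(
        target=target,
        family=family,
        estimator=est,
        scaler=scaler,
        feature_names=list(dataset.feature_names),
        best_params=dict(best_params),
        seed=seed,
    )


@dataclass
class FoldResult:
    provider: str
    n_test: int
    accuracy: float
    macro_f1: float


@dataclass
class EvaluationReport:
    target: SignalTarget
    family: str
    folds: list[FoldResult] = field(default_factory=list)
    skipped_providers: list[str] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.accuracy for f in self.folds])) if self.folds else 0.0

    @property
    def mean_macro_f1(self) -> float:
        return float(np.mean([f.macro_f1 for f in self.folds])) if self.folds else 0.0

    def to_dict(self) -> dict:
        return {
            "target": self.target.column,
            "family": self.family,
            "mean_accuracy": self.mean_accuracy,
            "mean_macro_f1": self.mean_macro_f1,
            "folds": [vars(f) for f in self.folds],
            "skipped_providers": self.skipped_providers,
        }


def loso_evaluate(
    dataset: Dataset,
    family: str,
    target: SignalTarget,
    grid: Mapping[str, Sequence] | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Leave-one-provider-out evaluation of one family on one target.

    Each fold trains (scaling, SMOTE, grid search included) strictly on the
    other providers' slices; a fold whose training labels collapse to one
    class is skipped with a warning and excluded from the means.
    """
    providers = sorted(set(dataset.groups))
    if len(providers) < 2:
        raise ValueError("leave-one-provider-out needs at least 2 providers")
    report = EvaluationReport(target=target, family=family)
    for provider in providers:
        test_mask = dataset.groups == provider
        y_train = dataset.y[~test_mask]
        if len(np.unique(y_train)) < 2:
            log.warning("fold %s: single-class training data, skipping", provider)
            report.skipped_providers.append(str(provider))
            continue
        train = Dataset(
            X=dataset.X[~test_mask],
            y=y_train,
            groups=dataset.groups[~test_mask],
            feature_names=dataset.feature_names,
            keys=dataset.keys[~test_mask].reset_index(drop=True),
        )
        model = train_signal_model(train, family, target, grid=grid, seed=seed)
        y_pred = model.predict(dataset.X[test_mask])
        y_true = dataset.y[test_mask]
        report.folds.append(
            FoldResult(
                provider=str(provider),
                n_test=int(test_mask.sum()),
                accuracy=float(accuracy_score(y_true, y_pred)),
                macro_f1=float(
                    f1_score(y_true, y_pred, average="macro",
                             labels=list(CLASSES), zero_division=0)
                ),
            )
        )
    return report


def select_model(reports: Iterable[EvaluationReport]) -> str:
    """Pick the family with the highest mean macro-F1.

    Exact ties go to the globally interpretable families in the order
    DTC > LR > SVM-linear, then input order.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no evaluation reports given")

    def rank(r: EvaluationReport) -> int:
        try:
            return INTERPRETABLE_FAMILIES.index(r.family)
        except ValueError:
            return len(INTERPRETABLE_FAMILIES)

    best = min(reports, key=lambda r: (-r.mean_macro_f1, rank(r)))
    return best.family


def predict_slices(model: TrainedSignalModel, features: pd.DataFrame) -> pd.Series:
    """Predict neutral/high per slice row, realigning columns by name."""
    cols = [c for c in features.columns if c not in ("visit_id", "slice_index", "provider_id")]
    missing = set(model.feature_names) - set(cols)
    extra = set(cols) - set(model.feature_names)
    if missing or extra:
        raise SchemaError(
            f"feature schema mismatch: missing={sorted(missing)} extra={sorted(extra)}"
        )
    X = features[model.feature_names].to_numpy(dtype=float)
    return pd.Series(model.predict(X), index=features.index, name=model.target.column)


def export_decision_paths(model: TrainedSignalModel, top_k: int = 10) -> dict:
    """Human-readable account of what drives a fitted model.

    Decision trees export their node conditions and leaf classes verbatim;
    linear models rank features by |coefficient| with sign; ensembles fall
    back to impurity importances tagged as only locally interpretable.
    """
    est = model.estimator
    names = model.feature_names
    if model.family == "DTC":
        text = export_text(est, feature_names=names)
        order = np.argsort(est.feature_importances_)[::-1]
        ranked = [
            {"feature": names[i], "weight": float(est.feature_importances_[i])}
            for i in order[:top_k]
            if est.feature_importances_[i] > 0
        ]
        return {"family": "DTC", "interpretability": "global",
                "tree_text": text, "ranked_features": ranked}
    if model.family in ("LR", "SVM-linear"):
        coef = np.asarray(est.coef_).ravel()
        order = np.argsort(np.abs(coef))[::-1]
        ranked = [
            {"feature": names[i], "weight": float(coef[i]),
             "direction": "high" if coef[i] > 0 else "neutral"}
            for i in order[:top_k]
        ]
        return {"family": model.family, "interpretability": "global",
                "ranked_features": ranked}
    importances = getattr(est, "feature_importances_", None)
    if importances is None:
        raise ValueError(f"no interpretability export for family {model.family}")
    order = np.argsort(importances)[::-1]
    ranked = [
        {"feature": names[i], "weight": float(importances[i])}
        for i in order[:top_k]
    ]
    return {"family": model.family, "interpretability": "local",
            "ranked_features": ranked}


def save_sidecar(model: TrainedSignalModel, report: EvaluationReport | None, path) -> None:
    payload = model.sidecar()
    if report is not None:
        payload["evaluation"] = report.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
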