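"""Cross-validated classification and metric reporting.

Four classifiers — Bagged Trees (BT), RBF-kernel SVM, a single-hidden-layer
feed-forward neural network (ANN) and k-nearest neighbours (kNN) — are
evaluated with stratified 10-fold cross-validation on a shared fold
assignment.  Confusion counts are pooled across folds before the five
metrics are computed, with myocardial infarction (``"MI"``) fixed as the
positive class:

    Acc = (TP + TN) / total          Rec = TP / (TP + FN)
    Spe = TN / (TN + FP)             PPV = TP / (TP + FP)
    NPV = TN / (TN + FN)

all reported as percentages.  Distance- and gradient-based learners (SVM,
ANN, kNN) standardize features with train-fold statistics only; Bagged
Trees are scale-invariant and take raw features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .types import POSITIVE_LABEL

__all__ = [
    "CLASSIFIER_IDS",
    "ConfusionCounts",
    "MetricsReport",
    "make_folds",
    "build_classifier",
    "train_predict",
    "compute_metrics",
    "cross_validate",
    "run_experiment",
    "accuracy_table",
]

CLASSIFIER_IDS = ("BT", "SVM", "ANN", "kNN")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled TP/FP/TN/FN with MI as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricsReport:
    """The five derived metrics (percent; NaN marks a zero denominator)."""

    acc: float
    rec: float
    spe: float
    ppv: float
    npv: float
    counts: ConfusionCounts
    classifier_id: str = ""
    feature_set: str = ""
    n_features: int = 0
    fold_counts: list[ConfusionCounts] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "classifier": self.classifier_id,
            "feature_set": self.feature_set,
            "n_features": self.n_features,
            "acc": round(self.acc, 1), "rec": round(self.rec, 1),
            "spe": round(self.spe, 1), "ppv": round(self.ppv, 1),
            "npv": round(self.npv, 1),
            "tp": self.counts.tp, "fp": self.counts.fp,
            "tn": self.counts.tn, "fn": self.counts.fn,
        }


def make_folds(labels, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment (array of fold ids, one per sample)."""
    y = np.asarray(labels)
    for cls, count in zip(*np.unique(y, return_counts=True)):
        if count < k:
            raise ValueError(f"class {cls!r} has {count} members, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(y.size, dtype=int)
    for i, (_, test_idx) in enumerate(skf.split(np.zeros(y.size), y)):
        fold[test_idx] = i
    return fold


def build_classifier(classifier_id: str, seed: int = 0):
    """Seeded estimator for one of the four classifier ids."""
    if classifier_id == "BT":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=30, random_state=seed)
    if classifier_id == "SVM":
        return Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(C=1.0, kernel="rbf", gamma="auto")),  # gamma = 1 / n_features
        ])
    if classifier_id == "ANN":
        return Pipeline([
            ("scale", StandardScaler()),
            ("mlp", MLPClassifier(hidden_layer_sizes=(10,), max_iter=500,
                                  random_state=seed)),
        ])
    if classifier_id == "kNN":
        return Pipeline([
            ("scale", StandardScaler()),
            ("knn", KNeighborsClassifier(n_neighbors=5, metric="euclidean")),
        ])
    raise ValueError(f"unknown classifier id {classifier_id!r}; known: {CLASSIFIER_IDS}")


def train_predict(classifier_id: str, x_train, y_train, x_test, seed: int = 0) -> np.ndarray:
    """Fit one classifier on the train split and predict the test split."""
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training split contains a single class")
    clf = build_classifier(classifier_id, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(np.asarray(x_train, dtype=float), y_train)
        return clf.predict(np.asarray(x_test, dtype=float))


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def compute_metrics(counts: ConfusionCounts, classifier_id: str = "",
                    feature_set: str = "", n_features: int = 0,
                    fold_counts: list[ConfusionCounts] | None = None) -> MetricsReport:
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    return MetricsReport(
        acc=_pct(counts.tp + counts.tn, counts.total),
        rec=_pct(counts.tp, counts.tp + counts.fn),
        spe=_pct(counts.tn, counts.tn + counts.fp),
        ppv=_pct(counts.tp, counts.tp + counts.fp),
        npv=_pct(counts.tn, counts.tn + counts.fn),
        counts=counts,
        classifier_id=classifier_id,
        feature_set=feature_set,
        n_features=n_features,
        fold_counts=fold_counts or [],
    )


def _count(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    pos = y_true == POSITIVE_LABEL
    pred_pos = y_pred == POSITIVE_LABEL
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def cross_validate(classifier_id: str, x, y, fold: np.ndarray, seed: int = 0,
                   feature_set: str = "", return_models: bool = False):
    """k-fold CV on a precomputed fold assignment; pooled-count metrics."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    fold_counts = []
    models = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for f in sorted(np.unique(fold)):
        test = fold == f
        train = ~test
        clf = build_classifier(classifier_id, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(x[train], y[train])
            pred = clf.predict(x[test])
        c = _count(y[test], pred)
        fold_counts.append(c)
        pooled = pooled + c
        if return_models:
            models.append(clf)
    report = compute_metrics(pooled, classifier_id, feature_set, x.shape[1], fold_counts)
    return (report, models) if return_models else report


def run_experiment(
    features: pd.DataFrame,
    classifier_ids=CLASSIFIER_IDS,
    feature_subsets: dict[str, list[str]] | None = None,
    k: int = 10,
    seed: int = 0,
) -> list[MetricsReport]:
    """Evaluate every (classifier, feature-subset) cell on shared folds.

    ``features`` is a matrix from
    :func:`ecgmi.features.extract_feature_matrix` (``label`` column plus
    named feature columns).  ``feature_subsets`` maps a subset name to a
    list of feature columns; default is one subset with every feature
    column.  Rows with missing values in a subset are dropped from that
    subset's evaluation.
    """
    meta_cols = [c for c in ("record_id", "segment_index", "label") if c in features.columns]
    all_cols = [c for c in features.columns if c not in meta_cols]
    subsets = feature_subsets or {"all": all_cols}
    y_all = features["label"].to_numpy()
    reports = []
    for subset_name, cols in subsets.items():
        sub = features[cols]
        keep = ~sub.isna().any(axis=1).to_numpy()
        x = sub.to_numpy(dtype=float)[keep]
        y = y_all[keep]
        fold = make_folds(y, k=k, seed=seed)
        for cid in classifier_ids:
            reports.append(cross_validate(cid, x, y, fold, seed=seed,
                                          feature_set=subset_name))
    return reports


def accuracy_table(reports: list[MetricsReport]) -> pd.DataFrame:
    """Feature-set x classifier accuracy grid (percent, one decimal)."""
    df = pd.DataFrame([{"feature_set": r.feature_set, "classifier": r.classifier_id,
                        "n_features": r.n_features, "acc": round(r.acc, 1)}
                       for r in reports])
    wide = df.pivot_table(index=["feature_set", "n_features"], columns="classifier",
                          values="acc", sort=False)
    return wide.reset_index()
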