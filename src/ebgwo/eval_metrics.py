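"""Confusion-matrix metrics, rank-based AUC, and the downstream
classifier contract used for final evaluation.

The positive class is the case (PWP) label 1 throughout.  AUC is the
Mann–Whitney rank-sum form: rank all scores ascending with average ranks
for ties, sum the ranks of the positives S_p, then
AUC = (S_p - n_p (n_p + 1) / 2) / (n_p n_n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "ScoredPredictions",
    "ClassifierSpec",
    "CLASSIFIER_KINDS",
    "confusion",
    "classification_metrics",
    "auc_rank",
    "fit_predict",
]


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion matrix must contain at least one instance")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn}


@dataclass
class ScoredPredictions:
    """Continuous case scores (higher = more case-like) with true labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1)")


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionMatrix:
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    return ConfusionMatrix(
        tp=int(((labels == 1) & (predictions == 1)).sum()),
        tn=int(((labels == 0) & (predictions == 0)).sum()),
        fp=int(((labels == 0) & (predictions == 1)).sum()),
        fn=int(((labels == 1) & (predictions == 0)).sum()),
    )


def classification_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Accuracy, precision, recall and F1.

    A metric whose denominator is zero is reported as ``None`` (undefined),
    never silently as 0.
    """
    accuracy = (cm.tp + cm.tn) / cm.total
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else None
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


def auc_rank(sp: ScoredPredictions) -> float:
    """Area under the ROC curve via the Mann–Whitney rank-sum identity,
    with average ranks (half credit) for score ties."""
    n_pos = int(sp.labels.sum())
    n_neg = sp.labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(sp.scores, method="average")
    s_pos = ranks[sp.labels == 1].sum()
    return float((s_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


CLASSIFIER_KINDS = ("knn", "svm_rbf", "decision_tree", "lightgbm")


@dataclass
class ClassifierSpec:
    """A downstream classifier: k-nearest-neighbour, RBF-kernel SVM,
    decision tree, or leaf-wise gradient-boosted trees (LightGBM).
    Hyperparameters default to library conventions and are all
    overridable via ``hyperparameters``."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier kind {self.kind!r}; expected one of "
                f"{CLASSIFIER_KINDS}"
            )


def _build(spec: ClassifierSpec):
    hp = dict(spec.hyperparameters)
    if spec.kind == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(
            n_neighbors=hp.pop("k", 5), metric=hp.pop("metric", "minkowski"), **hp
        )
    if spec.kind == "svm_rbf":
        from sklearn.svm import SVC

        return SVC(
            kernel="rbf",
            C=hp.pop("C", 1.0),
            gamma=hp.pop("gamma", "scale"),
            random_state=spec.seed,
            **hp,
        )
    if spec.kind == "decision_tree":
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    from lightgbm import LGBMClassifier

    return LGBMClassifier(
        random_state=spec.seed,
        n_jobs=1,
        verbose=-1,
        min_child_samples=hp.pop("min_child_samples", 20),
        **hp,
    )


def fit_predict(spec, train, test) -> tuple[np.ndarray, np.ndarray]:
    """Train the named classifier and score the test table.

    Returns hard 0/1 predictions and continuous case scores (class-1
    probability, or the decision-function margin for the SVM).
    """
    if train.n_features != test.n_features or train.feature_names != test.feature_names:
        raise ValueError("train and test must share the same feature columns")
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training partition must contain both classes")
    model = _build(spec)
    model.fit(train.values, train.labels)
    import warnings

    with warnings.catch_warnings():
        # lightgbm's sklearn wrapper invents feature names at fit time and
        # then warns that plain arrays lack them at predict time
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names"
        )
        predictions = np.asarray(model.predict(test.values), dtype=int)
        if spec.kind == "svm_rbf":
            scores = np.asarray(model.decision_function(test.values), dtype=float)
        else:
            scores = np.asarray(model.predict_proba(test.values)[:, 1], dtype=float)
    return predictions, scores
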