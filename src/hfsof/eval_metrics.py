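"""Final SVM training and the full multi-class metric suite.

Multi-class SVMs are decomposed one-vs-rest so that predicted labels and
the per-class decision scores used for AUC come from the same score matrix.
Per-class precision/recall/F1 follow the 0/0 -> 0 convention; macro
aggregates are unweighted means and weighted aggregates are support-weighted
means (weighted recall equals accuracy identically).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

DEFAULT_SVM_C = 100.0
DEFAULT_SVM_GAMMA = 0.01


@dataclass
class ConfusionMatrix:
    """C x C counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if not self.class_names:
            self.class_names = [str(c) for c in range(self.counts.shape[0])]

    @property
    def n_classes(self) -> int:
        return int(self.counts.shape[0])

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def save(self, path, delimiter: str = "\t") -> None:
        import pandas as pd

        df = pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names)
        df.to_csv(path, sep=delimiter)


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    supports: np.ndarray
    auc: np.ndarray | None
    macro: dict[str, float]
    weighted: dict[str, float]
    class_names: list[str]
    confusion: ConfusionMatrix | None = None

    def to_dict(self) -> dict:
        def r4(x: float) -> float:
            return round(float(x), 4)

        per_class = []
        for c, name in enumerate(self.class_names):
            entry = {
                "class": name,
                "precision": r4(self.precision[c]),
                "recall": r4(self.recall[c]),
                "f1": r4(self.f1[c]),
                "support": int(self.supports[c]),
            }
            if self.auc is not None:
                entry["auc"] = r4(self.auc[c]) if np.isfinite(self.auc[c]) else None
            per_class.append(entry)
        return {
            "accuracy": r4(self.accuracy),
            "per_class": per_class,
            "macro": {k: r4(v) for k, v in self.macro.items()},
            "weighted": {k: r4(v) for k, v in self.weighted.items()},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


class OvrSvm:
    """One-vs-rest ensemble of binary RBF SVMs with a shared score matrix."""

    def __init__(self, C: float = DEFAULT_SVM_C, gamma: float = DEFAULT_SVM_GAMMA):
        self.C = float(C)
        self.gamma = float(gamma)
        self.classes_: np.ndarray | None = None
        self.estimators_: list[SVC] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OvrSvm":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        self.classes_ = np.unique(y)
        if self.classes_.shape[0] < 2:
            raise ValueError("training labels contain a single class")
        self.estimators_ = []
        for c in self.classes_:
            est = SVC(C=self.C, gamma=self.gamma, kernel="rbf")
            est.fit(X, (y == c).astype(np.int64))
            self.estimators_.append(est)
        return self

    def decision_matrix(self, X: np.ndarray) -> np.ndarray:
        """N x C matrix of per-class decision scores (columns follow classes_)."""
        X = np.asarray(X, dtype=np.float64)
        return np.column_stack([est.decision_function(X) for est in self.estimators_])


def fit_final_svm(
    X_train: np.ndarray,
    y_train: np.ndarray,
    C_svm: float = DEFAULT_SVM_C,
    gamma_svm: float = DEFAULT_SVM_GAMMA,
) -> OvrSvm:
    return OvrSvm(C=C_svm, gamma=gamma_svm).fit(X_train, y_train)


def predict_with_scores(
    classifier: OvrSvm, X: np.ndarray, n_classes: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels (argmax of scores) plus the N x C score matrix.

    When ``n_classes`` exceeds the number of classes seen in training, the
    missing columns are filled with -inf so indices stay aligned with the
    global label space.
    """
    raw = classifier.decision_matrix(X)
    classes = classifier.classes_
    total = int(n_classes) if n_classes is not None else int(classes.max()) + 1
    scores = np.full((raw.shape[0], total), -np.inf)
    scores[:, classes] = raw
    predicted = classes[np.argmax(raw, axis=1)]
    return predicted, scores


def confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int,
              class_names: list[str] | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes - 1}]")
    flat = y_true * n_classes + y_pred
    counts = np.bincount(flat, minlength=n_classes * n_classes)
    return ConfusionMatrix(
        counts=counts.reshape(n_classes, n_classes),
        class_names=list(class_names) if class_names else [],
    )


def per_class_metrics(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class precision, recall and F1 with the 0/0 -> 0 convention."""
    counts = cm.counts.astype(np.float64)
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2.0 * precision * recall / denom, 0.0)
    if np.any((tp + fp) == 0):
        logger.debug("some classes were never predicted; precision set to 0")
    return precision, recall, f1


def aggregate(values: np.ndarray, supports: np.ndarray) -> tuple[float, float]:
    """(macro, weighted) aggregates of per-class values."""
    values = np.asarray(values, dtype=np.float64)
    supports = np.asarray(supports, dtype=np.float64)
    if values.shape != supports.shape:
        raise ValueError("values and supports must have equal length")
    macro = float(values.mean())
    weighted = float((values * supports).sum() / supports.sum())
    return macro, weighted


def macro_f1_from_predictions(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> float:
    cm = confusion(y_true, y_pred, n_classes)
    _, _, f1 = per_class_metrics(cm)
    return float(f1.mean())


def ovr_auc(
    y_true: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Per-class one-vs-rest AUC plus macro and support-weighted aggregates.

    Classes absent from ``y_true`` (or covering all of it) get NaN and are
    excluded from the macro mean with a warning.
    """
    y_true = np.asarray(y_true, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] != y_true.shape[0]:
        raise ValueError("scores must be N x C aligned with y_true")
    n_classes = scores.shape[1]
    aucs = np.full(n_classes, np.nan)
    supports = np.bincount(y_true, minlength=n_classes).astype(np.float64)
    for c in range(n_classes):
        positives = y_true == c
        if positives.all() or not positives.any():
            logger.warning("class %d has no positives or no negatives; AUC undefined", c)
            continue
        col = scores[:, c]
        finite = np.isfinite(col)
        if not finite.all():
            # -inf placeholder columns (class unseen in training) rank last
            col = np.where(finite, col, np.nanmin(col[finite]) - 1.0 if finite.any() else 0.0)
        aucs[c] = roc_auc_score(positives.astype(int), col)
    defined = np.isfinite(aucs)
    macro = float(np.mean(aucs[defined])) if defined.any() else float("nan")
    weighted = (
        float((aucs[defined] * supports[defined]).sum() / supports[defined].sum())
        if defined.any()
        else float("nan")
    )
    return aucs, macro, weighted


def evaluate_classifier(
    classifier: OvrSvm,
    X_test: np.ndarray,
    y_test: np.ndarray,
    n_classes: int,
    class_names: list[str] | None = None,
) -> MetricsReport:
    """Predict, score and assemble the full report on held-out data."""
    y_pred, scores = predict_with_scores(classifier, X_test, n_classes=n_classes)
    cm = confusion(y_test, y_pred, n_classes, class_names)
    precision, recall, f1 = per_class_metrics(cm)
    supports = cm.supports
    accuracy = float(np.trace(cm.counts) / cm.total)
    auc_per_class, auc_macro, auc_weighted = ovr_auc(y_test, scores)
    macro = {
        "precision": aggregate(precision, supports)[0],
        "recall": aggregate(recall, supports)[0],
        "f1": aggregate(f1, supports)[0],
        "auc": auc_macro,
    }
    weighted = {
        "precision": aggregate(precision, supports)[1],
        "recall": aggregate(recall, supports)[1],
        "f1": aggregate(f1, supports)[1],
        "auc": auc_weighted,
    }
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        supports=supports,
        auc=auc_per_class,
        macro=macro,
        weighted=weighted,
        class_names=list(class_names) if class_names else [str(c) for c in range(n_classes)],
        confusion=cm,
    )
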