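"""One-vs-Rest multiclass evaluation of the selected feature set.

Five classifiers are fitted behind a uniform contract -- gradient
boosting, a Gaussian process, a linear support-vector classifier,
logistic regression and an SGD linear classifier, all as delivered by
scikit-learn and wrapped in an explicit One-vs-Rest reduction.  Metrics
are computed from per-class confusion counts: accuracy, precision,
recall and F1 use the standard binary formulas under the OvR reduction
and are macro-averaged over classes (micro averaging is available by
flag); AUC is the trapezoidal area under the per-class ROC curve, with
tied scores grouped into a single threshold step, macro-averaged.  A
zero denominator (e.g. no positive prediction) defines the metric as 0
and raises a logged flag rather than an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

DEFAULT_CLASSIFIERS = ("gradient_boosting", "gaussian_process",
                       "linear_svc", "logistic_regression", "sgd")


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the supported classifiers (library defaults)."""
    if name == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if name == "gaussian_process":
        return GaussianProcessClassifier(random_state=seed)
    if name == "linear_svc":
        return LinearSVC(random_state=seed)
    if name == "logistic_regression":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "sgd":
        return SGDClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts for one class under One-vs-Rest."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion(y_true: np.ndarray, y_pred: np.ndarray,
              positive_class) -> ConfusionMatrix:
    """Reduce multiclass truth/prediction to OvR binary counts."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    if positive_class not in y_true and positive_class not in y_pred:
        raise ValueError(f"class {positive_class!r} absent from inputs")
    pos_t = y_true == positive_class
    pos_p = y_pred == positive_class
    return ConfusionMatrix(
        TP=int((pos_t & pos_p).sum()),
        TN=int((~pos_t & ~pos_p).sum()),
        FP=int((~pos_t & pos_p).sum()),
        FN=int((pos_t & ~pos_p).sum()),
    )


def _safe_ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("%s has zero denominator; defined as 0", name)
        return 0.0
    return num / den


def accuracy(cm: ConfusionMatrix) -> float:
    return _safe_ratio(cm.TP + cm.TN, cm.n, "accuracy")


def precision(cm: ConfusionMatrix) -> float:
    return _safe_ratio(cm.TP, cm.TP + cm.FP, "precision")


def recall(cm: ConfusionMatrix) -> float:
    return _safe_ratio(cm.TP, cm.TP + cm.FN, "recall")


def f1(cm: ConfusionMatrix) -> float:
    p = precision(cm)
    r = recall(cm)
    if p + r == 0:
        logger.warning("F1 has zero denominator; defined as 0")
        return 0.0
    return 2.0 * p * r / (p + r)


@dataclass
class RocCurve:
    """ROC points from (0,0) to (1,1) and their trapezoidal area."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})


def roc_auc(scores: np.ndarray, y_true: np.ndarray) -> RocCurve:
    """ROC curve and trapezoidal AUC for binary truth and real scores.

    The threshold sweep groups equal scores into one step, which makes
    the trapezoidal area identical to the tie-corrected Mann-Whitney
    rank statistic U / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y_true).astype(bool)
    if scores.shape != y.shape:
        raise ValueError("scores and y_true length mismatch")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    # indices where a new (lower) distinct score starts: threshold steps
    distinct = np.flatnonzero(np.diff(s_sorted)) + 1
    boundaries = np.concatenate(([0], distinct, [len(y_sorted)]))
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(~y_sorted)
    tpr = np.concatenate(([0.0], tp[boundaries[1:] - 1] / n_pos))
    fpr = np.concatenate(([0.0], fp[boundaries[1:] - 1] / n_neg))
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc)


@dataclass
class ClassifierScores:
    """Per-classifier metrics plus per-class confusion matrices."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    per_class: dict = field(default_factory=dict)
    roc: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "auc": self.auc}


@dataclass
class EvaluationReport:
    """Metrics of every evaluated classifier on the held-out split."""

    scores: dict
    classes: list
    split: str
    seed: int
    averaging: str = "macro"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: cs.as_dict() for name, cs in self.scores.items()}).T

    def to_json(self, path: str | Path) -> None:
        import json
        payload = {
            "split": self.split, "seed": self.seed,
            "averaging": self.averaging,
            "classes": [str(c) for c in self.classes],
            "classifiers": {
                name: {**cs.as_dict(),
                       "per_class": {str(c): vars(cm)
                                     for c, cm in cs.per_class.items()}}
                for name, cs in self.scores.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _decision_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        scores = model.decision_function(X)
    else:
        scores = model.predict_proba(X)
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim == 1:  # binary: expand to two columns
        scores = np.column_stack([-scores, scores])
    return scores


def evaluate_classifiers(X_train: np.ndarray, y_train: np.ndarray,
                         X_test: np.ndarray, y_test: np.ndarray,
                         classifiers=DEFAULT_CLASSIFIERS,
                         seed: int = 0,
                         averaging: str = "macro") -> EvaluationReport:
    """Fit the configured classifiers (OvR) and score the held-out split.

    Multiclass AUC is the unweighted mean of per-class OvR AUCs;
    accuracy is the plain multiclass accuracy (identical to the mean OvR
    accuracy complement of the misclassification rate).
    """
    if averaging not in ("macro", "micro"):
        raise ValueError("averaging must be 'macro' or 'micro'")
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    classes = np.unique(y_train)
    missing = set(np.unique(y_test)) - set(classes)
    if missing:
        raise ValueError(
            f"classes {sorted(missing)} absent from the training split; "
            "use a stratified split")
    report_scores = {}
    for name in classifiers:
        base = make_classifier(name, seed)
        model = OneVsRestClassifier(base)
        model.fit(X_train, y_train)
        y_pred = model.predict(X_test)
        scores = _decision_scores(model, X_test)
        per_class, rocs = {}, {}
        per_class_metrics = []
        for k, cls in enumerate(model.classes_):
            cm = confusion(y_test, y_pred, cls)
            per_class[cls] = cm
            y_bin = (y_test == cls).astype(int)
            if 0 < y_bin.sum() < len(y_bin):
                rocs[cls] = roc_auc(scores[:, k], y_bin)
            per_class_metrics.append((precision(cm), recall(cm), f1(cm)))
        overall_accuracy = float(np.mean(y_pred == y_test))
        if averaging == "macro":
            prec = float(np.mean([m[0] for m in per_class_metrics]))
            rec = float(np.mean([m[1] for m in per_class_metrics]))
            f1_avg = float(np.mean([m[2] for m in per_class_metrics]))
        else:
            pooled = ConfusionMatrix(
                TP=sum(cm.TP for cm in per_class.values()),
                TN=sum(cm.TN for cm in per_class.values()),
                FP=sum(cm.FP for cm in per_class.values()),
                FN=sum(cm.FN for cm in per_class.values()))
            prec, rec, f1_avg = (precision(pooled), recall(pooled),
                                 f1(pooled))
        auc = float(np.mean([rc.auc for rc in rocs.values()])) \
            if rocs else float("nan")
        report_scores[name] = ClassifierScores(
            accuracy=overall_accuracy, precision=prec, recall=rec,
            f1=f1_avg, auc=auc, per_class=per_class, roc=rocs)
    return EvaluationReport(scores=report_scores, classes=list(classes),
                            split=f"train={len(y_train)}/test={len(y_test)}",
                            seed=seed, averaging=averaging)
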