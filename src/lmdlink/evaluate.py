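"""Tenfold cross-validated evaluation: confusion metrics, ROC/AUC, PR/AUPR.

Confusion-matrix metrics at the 0.5 score threshold:

    Acc  = (TP + TN) / total          Sen  = TP / (TP + FN)
    Spec = TN / (TN + FP)             Prec = TP / (TP + FP)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A degenerate denominator is reported as 0 together with an "undefined" flag,
never as a silent NaN.  AUC is the trapezoidal area under the ROC curve
(equal to the normalized Mann-Whitney U statistic); AUPR is the step-wise
average-precision area under the precision-recall curve.

Cross-validation stratifies by label.  The default mode mirrors the
reference protocol — features computed once on all data, only the labeled
pairs are split.  A leak-free mode recomputes the SVD and node2vec features
per fold with the test-fold positive pairs removed from the association
matrix and network before training, guarding against feature-level
information leakage (a known pitfall of association-prediction evaluation);
it is enabled by supplying a ``feature_builder`` callback.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold

from .classify import LabeledDataset, make_classifier
from .exceptions import ContractError
from .integrate import IntegratedFeatures, pair_vector

METRIC_NAMES = ("Acc", "Sen", "Spec", "Prec", "MCC", "AUC", "AUPR")

FeatureBuilder = Callable[[Sequence[tuple[str, str]]], IntegratedFeatures]
# leak-free mode: maps the *training* positive pairs to fold-specific features


@dataclass(frozen=True)
class EvaluationReport:
    per_fold: tuple[dict, ...]
    mean: dict
    std: dict
    roc_points: tuple[tuple[np.ndarray, np.ndarray], ...]  # (fpr, tpr) per fold
    pr_points: tuple[tuple[np.ndarray, np.ndarray], ...]  # (recall, prec) per fold
    fingerprint: dict = field(default_factory=dict)

    def to_json(self) -> str:
        """Deterministic JSON serialization (byte-identical across reruns)."""
        payload = {
            "fingerprint": self.fingerprint,
            "per_fold": list(self.per_fold),
            "mean": self.mean,
            "std": self.std,
            "roc_points": [
                {"fpr": f.tolist(), "tpr": t.tolist()} for f, t in self.roc_points
            ],
            "pr_points": [
                {"recall": r.tolist(), "precision": p.tolist()}
                for r, p in self.pr_points
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=1)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Acc/Sen/Spec/Prec/MCC from raw counts, with an undefined-metric list."""
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ContractError(f"{name} must be >= 0, got {v}")
    total = tp + fp + tn + fn
    if total == 0:
        raise ContractError("at least one count must be positive")
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (tp + tn) / total
    sen = ratio(tp, tp + fn, "Sen")
    spec = ratio(tn, tn + fp, "Spec")
    prec = ratio(tp, tp + fp, "Prec")
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ratio(tp * tn - fp * fn, mcc_den, "MCC")
    return {
        "Acc": acc,
        "Sen": sen,
        "Spec": spec,
        "Prec": prec,
        "MCC": mcc,
        "undefined": undefined,
    }


def roc_curve_auc(
    y_true: np.ndarray, scores: np.ndarray
) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC points and trapezoidal AUC.

    The trapezoidal area equals the probability that a random positive
    outscores a random negative (ties counted 1/2).
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    if len(np.unique(y_true)) < 2:
        raise ContractError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y_true, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr), auc


def pr_curve_aupr(
    y_true: np.ndarray, scores: np.ndarray
) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Precision-recall points and step-wise (average precision) AUPR."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    if int(np.sum(y_true == 1)) == 0:
        raise ContractError("PR curve requires at least one positive")
    precision, recall, _ = precision_recall_curve(y_true, scores)
    # step rule: sum precision at each recall increment (= average precision)
    ap = float(-np.sum(np.diff(recall) * np.array(precision)[:-1]))
    return (recall, precision), ap


def evaluate_scores(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> dict:
    """All metrics for one scored test set."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    metrics = confusion_metrics(tp, fp, tn, fn)
    (fpr, tpr), auc = roc_curve_auc(y_true, scores)
    (recall, precision), aupr = pr_curve_aupr(y_true, scores)
    metrics["AUC"] = auc
    metrics["AUPR"] = aupr
    return {
        "metrics": metrics,
        "roc": (fpr, tpr),
        "pr": (recall, precision),
    }


def cross_validate(
    dataset: LabeledDataset,
    classifier: str = "XGB",
    folds: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
    feature_builder: FeatureBuilder | None = None,
    fingerprint: dict | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of a classifier on labeled pairs.

    With ``feature_builder`` set (leak-free mode), each fold's features are
    rebuilt from the training positives only and both train and test rows are
    re-featurized from them.
    """
    if folds < 2:
        raise ContractError(f"folds must be >= 2, got {folds}")
    y = dataset.y
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ContractError(
            f"each class needs >= {folds} samples for {folds}-fold stratified CV"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold: list[dict] = []
    rocs: list[tuple[np.ndarray, np.ndarray]] = []
    prs: list[tuple[np.ndarray, np.ndarray]] = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(dataset.X, y)):
        if feature_builder is None:
            X_train, X_test = dataset.X[train_idx], dataset.X[test_idx]
        else:
            train_pos = [
                dataset.samples[i] for i in train_idx if dataset.y[i] == 1
            ]
            feats = feature_builder(train_pos)
            X_train = np.stack(
                [pair_vector(feats, *dataset.samples[i]) for i in train_idx]
            )
            X_test = np.stack(
                [pair_vector(feats, *dataset.samples[i]) for i in test_idx]
            )
        model = make_classifier(classifier, seed)
        model.fit(X_train, y[train_idx])
        scores = model.predict_proba(X_test)[:, 1]
        res = evaluate_scores(y[test_idx], scores, threshold)
        entry = {"fold": fold, **res["metrics"]}
        per_fold.append(entry)
        rocs.append(res["roc"])
        prs.append(res["pr"])
    mean = {
        m: float(np.mean([f[m] for f in per_fold])) for m in METRIC_NAMES
    }
    std = {m: float(np.std([f[m] for f in per_fold])) for m in METRIC_NAMES}
    fp = dict(fingerprint or {})
    fp.setdefault("classifier", classifier)
    fp.setdefault("folds", folds)
    fp.setdefault("cv_seed", seed)
    fp.setdefault("threshold", threshold)
    fp.setdefault("leak_free", feature_builder is not None)
    return EvaluationReport(
        tuple(per_fold), mean, std, tuple(rocs), tuple(prs), fp
    )


def write_curves_csv(report: EvaluationReport, roc_path, pr_path) -> None:
    """Per-fold curve coordinates as CSV (fold,fpr,tpr) / (fold,recall,precision)."""
    with open(roc_path, "w", encoding="utf-8") as fh:
        fh.write("fold,fpr,tpr\n")
        for fold, (fpr, tpr) in enumerate(report.roc_points):
            for x, t in zip(fpr, tpr):
                fh.write(f"{fold},{x!r},{t!r}\n")
    with open(pr_path, "w", encoding="utf-8") as fh:
        fh.write("fold,recall,precision\n")
        for fold, (rec, prec) in enumerate(report.pr_points):
            for r, p in zip(rec, prec):
                fh.write(f"{fold},{r!r},{p!r}\n")
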