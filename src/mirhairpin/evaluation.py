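"""Classifier evaluation: Ac/Se/Sp/MCC, ROC/AUC, k-fold CV, top-N overlap.

The four threshold metrics are

    Ac  = (TP + TN) / (TP + FP + TN + FN)
    Se  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

with MCC = 0 whenever a factor of its denominator is zero (convention).
AUC is the Mann-Whitney probability that a random positive outscores a
random negative, ties counted half.  Cross-validation is stratified and
refits the entire training stack — potential tables, scaler, SVM — inside
each training fold, so no statistic fitted on a test fold ever leaks in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import TrainingError


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("negative confusion counts")
        if self.TP + self.FP + self.TN + self.FN < 1:
            raise ValueError("all-zero confusion counts")

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class MetricsReport:
    Ac: float
    Se: float
    Sp: float
    MCC: float
    AUC: float | None = None
    fold_aucs: list = field(default_factory=list)
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict:
        d = {"Ac": self.Ac, "Se": self.Se, "Sp": self.Sp, "MCC": self.MCC}
        if self.AUC is not None:
            d["AUC"] = self.AUC
        if self.fold_aucs:
            d["fold_aucs"] = list(self.fold_aucs)
        return d


def metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity and MCC from confusion counts."""
    total = c.TP + c.FP + c.TN + c.FN
    ac = (c.TP + c.TN) / total
    se = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    sp = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else 0.0
    denom = (c.TP + c.FN) * (c.TN + c.FP) * (c.TP + c.FP) * (c.TN + c.FN)
    mcc = ((c.TP * c.TN - c.FN * c.FP) / math.sqrt(denom)) if denom else 0.0
    return MetricsReport(Ac=ac, Se=se, Sp=sp, MCC=mcc, counts=c)


def roc_auc(scores, labels):
    """AUC plus the ROC staircase (fpr, tpr, thresholds).

    AUC equals the Mann-Whitney probability with ties counted half; raises
    on single-class labels.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise TrainingError("AUC needs both classes present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return auc, fpr, tpr, thresholds


def evaluate_predictions(y_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Threshold metrics plus AUC for one scored test set."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    rep = metrics(ConfusionCounts.from_labels(y_true, (scores >= threshold).astype(int)))
    rep.AUC = roc_auc(scores, y_true)[0]
    return rep


def kfold_cv(items: list, labels, folds: int, trainer, seed: int = 0) -> MetricsReport:
    """Stratified k-fold cross-validation with full per-fold refitting.

    ``trainer(train_items, train_labels, seed)`` must return a scoring
    callable ``scorer(test_items) -> scores``; everything the trainer fits
    (potential tables, scaler, SVM) is therefore re-estimated inside each
    training fold.  Fold assignment is deterministic under ``seed``.
    Returns pooled threshold metrics (score >= 0.5), the mean AUC and the
    per-fold AUCs.
    """
    labels = np.asarray(labels, dtype=int)
    if folds < 2:
        raise TrainingError("folds must be >= 2")
    if folds > int(np.bincount(labels).min()):
        raise TrainingError("folds exceed the minority class size")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs = []
    pooled_true: list[int] = []
    pooled_scores: list[float] = []
    for f, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        scorer = trainer([items[i] for i in train_idx], labels[train_idx],
                         seed + f)
        scores = np.asarray(scorer([items[i] for i in test_idx]), dtype=float)
        fold_aucs.append(roc_auc(scores, labels[test_idx])[0])
        pooled_true.extend(labels[test_idx].tolist())
        pooled_scores.extend(scores.tolist())
    rep = evaluate_predictions(pooled_true, pooled_scores)
    rep.fold_aucs = fold_aucs
    rep.AUC = float(np.mean(fold_aucs))
    return rep


def top_n_overlap(rankings: dict, n: int) -> dict:
    """Venn cardinalities of the top-N id sets of 2-3 rankings.

    ``rankings`` maps a ranking name to a mapping id -> score.  All
    rankings must cover identical id sets.  Ties at rank N are broken by id
    (ascending).  Returns the exclusive Venn regions keyed by "&"-joined
    name subsets, e.g. for rankings A and B: {"A": only-A, "B": only-B,
    "A&B": in both}.
    """
    names = sorted(rankings)
    if not 2 <= len(names) <= 3:
        raise ValueError("top_n_overlap supports 2 or 3 rankings")
    id_sets = {name: set(rankings[name]) for name in names}
    first = id_sets[names[0]]
    for name in names[1:]:
        if id_sets[name] != first:
            raise ValueError("rankings cover different candidate id sets")
    tops = {}
    for name in names:
        ordered = sorted(rankings[name].items(), key=lambda kv: (-kv[1], kv[0]))
        tops[name] = set(i for i, _ in ordered[:n])
    out = {}
    for mask in range(1, 2 ** len(names)):
        members = [names[i] for i in range(len(names)) if mask >> i & 1]
        region = set.intersection(*(tops[m] for m in members))
        for other in names:
            if other not in members:
                region = region - tops[other]
        out["&".join(members)] = len(region)
    return out
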