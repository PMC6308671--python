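"""Metrics, ROC/AUC, and agreement-partition bookkeeping.

The detection-positive class is bruised throughout: sensitivity is the
recall of bruised samples, specificity the recall of healthy samples.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .datatypes import BRUISED, HEALTHY


@dataclass
class EvaluationReport:
    tp: int  # bruised called bruised
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return asdict(self)


def score(pred, truth) -> EvaluationReport:
    pred = np.asarray(pred, int)
    truth = np.asarray(truth, int)
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    if HEALTHY not in truth or BRUISED not in truth:
        raise ValueError("truth must contain both classes")
    tp = int(np.sum((truth == BRUISED) & (pred == BRUISED)))
    fn = int(np.sum((truth == BRUISED) & (pred != BRUISED)))
    tn = int(np.sum((truth == HEALTHY) & (pred == HEALTHY)))
    fp = int(np.sum((truth == HEALTHY) & (pred != HEALTHY)))
    return EvaluationReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / len(truth),
    )


def roc_auc(scores, truth):
    """ROC points and AUC for continuous scores oriented bruised-high.

    AUC equals the normalized Mann-Whitney U statistic with half credit
    for ties.  Returns ``(points, auc)`` where points is an (m, 2) array of
    (false positive rate, true positive rate).
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth, int)
    if HEALTHY not in truth or BRUISED not in truth:
        raise ValueError("truth must contain both classes")
    y_true = (truth == BRUISED).astype(int)
    fpr, tpr, _ = roc_curve(y_true, scores)
    auc = float(roc_auc_score(y_true, scores))
    return np.column_stack([fpr, tpr]), auc


@dataclass
class AgreementPartition:
    """Table-3-style bookkeeping of fused results by base-classifier
    agreement."""

    n_agree: int
    n_agree_correct: int
    n_conflict: int
    n_conflict_correct: int

    @property
    def n(self) -> int:
        return self.n_agree + self.n_conflict

    def to_dict(self) -> dict:
        return asdict(self)


def agreement_partition(labels_a, labels_b, fused, truth) -> AgreementPartition:
    arrays = [np.asarray(a, int) for a in (labels_a, labels_b, fused, truth)]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("length mismatch")
    labels_a, labels_b, fused, truth = arrays
    agree = labels_a == labels_b
    correct = fused == truth
    return AgreementPartition(
        n_agree=int(agree.sum()),
        n_agree_correct=int((agree & correct).sum()),
        n_conflict=int((~agree).sum()),
        n_conflict_correct=int((~agree & correct).sum()),
    )
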