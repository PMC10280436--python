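"""Imbalance-aware evaluation metrics.

Implements the standard suite for imbalanced binary genomic classification:
accuracy, binary cross-entropy (natural log, clipped probabilities),
precision / recall / F1, sensitivity / specificity, and AUC-ROC computed as
the Mann-Whitney probability that a random positive outscores a random
negative (ties count one half) — equal to the trapezoidal area under the ROC
curve.

Zero-denominator ratios (e.g. precision with no predicted positives) return
0.0 and are flagged as undefined rather than raising, matching how degenerate
classifiers are conventionally reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .errors import ContractError, MetricError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(labels, predicted_labels) -> ConfusionCounts:
    """Confusion counts of binary predictions against binary labels."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(predicted_labels).astype(int)
    if y.shape != p.shape:
        raise ContractError(f"label/prediction length mismatch: {y.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: int, den: int) -> tuple[float, bool]:
    if den == 0:
        return 0.0, False
    return num / den, True


def accuracy(counts: ConfusionCounts) -> float:
    if counts.n == 0:
        raise ContractError("cannot compute accuracy of zero instances")
    return (counts.tp + counts.tn) / counts.n


def precision(counts: ConfusionCounts) -> float:
    return _ratio(counts.tp, counts.tp + counts.fp)[0]


def recall(counts: ConfusionCounts) -> float:
    return _ratio(counts.tp, counts.tp + counts.fn)[0]


def sensitivity(counts: ConfusionCounts) -> float:
    """Sn = TP / (TP + FN); identical to recall."""
    return recall(counts)


def specificity(counts: ConfusionCounts) -> float:
    return _ratio(counts.tn, counts.fp + counts.tn)[0]


def f1(counts: ConfusionCounts) -> float:
    p, p_ok = _ratio(counts.tp, counts.tp + counts.fp)
    r, r_ok = _ratio(counts.tp, counts.tp + counts.fn)
    if not (p_ok and r_ok) or (p + r) == 0:
        return 0.0
    return 2 * p * r / (p + r)


def binary_cross_entropy(labels, probabilities, clip_eps: float = 1e-15) -> float:
    """-(1/N) sum [y ln p + (1-y) ln(1-p)] with p clipped to [eps, 1-eps]."""
    y = np.asarray(labels, dtype=np.float64)
    p = np.asarray(probabilities, dtype=np.float64)
    if y.shape != p.shape:
        raise ContractError("labels and probabilities must have equal length")
    if p.size == 0:
        raise ContractError("cannot compute cross-entropy of zero instances")
    if (p < 0).any() or (p > 1).any():
        raise ContractError("probabilities must lie in [0, 1]")
    p = np.clip(p, clip_eps, 1 - clip_eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def auc_roc(labels, scores) -> float:
    """Mann-Whitney AUC with average ranks (ties count one half)."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ContractError("labels and scores must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC requires both classes to be present")
    ranks = rankdata(s)  # average ranks resolve ties as 1/2 credit
    rank_sum_pos = float(np.sum(ranks[y == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass
class EvalReport:
    accuracy: float
    binary_cross_entropy: float
    precision: float
    recall: float
    f1: float
    sensitivity: float
    specificity: float
    auc_roc: float
    confusion: ConfusionCounts
    n_instances: int
    n_positive: int
    undefined: tuple = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "bc": self.binary_cross_entropy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc_roc": self.auc_roc,
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
                "fn": self.confusion.fn,
            },
            "n": self.n_instances,
            "n_positive": self.n_positive,
            "undefined": list(self.undefined),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def evaluate(labels, probabilities, threshold: float = 0.5) -> EvalReport:
    """Full metric report: hard labels at ``threshold`` feed the confusion
    metrics; raw probabilities feed cross-entropy and AUC."""
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=np.float64)
    counts = confusion(y, (p >= threshold).astype(int))
    undefined = []
    prec, prec_ok = _ratio(counts.tp, counts.tp + counts.fp)
    rec, rec_ok = _ratio(counts.tp, counts.tp + counts.fn)
    spec, spec_ok = _ratio(counts.tn, counts.fp + counts.tn)
    if not prec_ok:
        undefined.append("precision")
    if not rec_ok:
        undefined.extend(["recall", "sensitivity"])
    if not spec_ok:
        undefined.append("specificity")
    f1_val = f1(counts)
    if not (prec_ok and rec_ok) or (prec + rec) == 0:
        undefined.append("f1")
    return EvalReport(
        accuracy=accuracy(counts),
        binary_cross_entropy=binary_cross_entropy(y, p),
        precision=prec,
        recall=rec,
        f1=f1_val,
        sensitivity=rec,
        specificity=spec,
        auc_roc=auc_roc(y, p),
        confusion=counts,
        n_instances=counts.n,
        n_positive=int(np.sum(y == 1)),
        undefined=tuple(undefined),
    )
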