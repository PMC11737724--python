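"""Segmentation-overlap and classification metrics.

Jaccard region coincidence P(R, A) = |A∩R| / |A∪R| and the Dice similarity
coefficient DSC(A, R) = 2|A∩R| / (|A| + |R|) score predicted lesion masks
against expert ground truth; accuracy, sensitivity (recall of malignant) and
specificity (recall of benign) score the binary classifier from confusion
counts, with malignant as the positive class.

Conventions: when both masks are empty the overlap metrics are defined as
1.0 (a perfect prediction of "nothing"); a metric with an undefined
denominator (e.g. sensitivity with no positive instances) is reported as NaN
with a warning, never silently as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

BENIGN, MALIGNANT = "benign", "malignant"
_VALID_LABELS = {BENIGN, MALIGNANT}


def _as_bool_pair(a, r) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a).astype(bool)
    r = np.asarray(r).astype(bool)
    if a.shape != r.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {r.shape}")
    return a, r


def jaccard(a, r) -> float:
    """Jaccard index |A∩R| / |A∪R| of two same-shape binary masks."""
    a, r = _as_bool_pair(a, r)
    union = np.logical_or(a, r).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, r).sum() / union)


def dice(a, r) -> float:
    """Dice similarity coefficient 2|A∩R| / (|A| + |R|)."""
    a, r = _as_bool_pair(a, r)
    denom = int(a.sum()) + int(r.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, r).sum() / denom)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Confusion counts plus the derived proportions for one evaluation run."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float


def confusion_counts(predicted, truth) -> ConfusionCounts:
    """Tally TP/TN/FP/FN over benign/malignant label sequences.

    Malignant is the positive class.
    """
    predicted = list(predicted)
    truth = list(truth)
    if len(predicted) != len(truth):
        raise ValueError("label sequences differ in length")
    bad = [v for v in set(predicted) | set(truth) if v not in _VALID_LABELS]
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    tp = tn = fp = fn = 0
    for p, t in zip(predicted, truth):
        if t == MALIGNANT:
            if p == MALIGNANT:
                tp += 1
            else:
                fn += 1
        else:
            if p == BENIGN:
                tn += 1
            else:
                fp += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def classification_metrics(c: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity TP/(TP+FN) and specificity TN/(TN+FP)."""
    if c.n == 0:
        raise ValueError("no evaluated instances")
    return MetricReport(
        tp=c.tp, tn=c.tn, fp=c.fp, fn=c.fn,
        accuracy=(c.tn + c.tp) / c.n,
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity"),
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity"),
    )
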