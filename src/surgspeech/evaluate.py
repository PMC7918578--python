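"""Evaluation: confusion matrix, P/R/F1, error rates, kappa, timelines.

Conventions, fixed across the package:

* the confusion matrix is always 8x8 (rows = ground truth phase,
  columns = predicted phase), even when some phases are absent from the
  evaluated set;
* macro-F1 is the unweighted mean of per-class F1 over the classes
  present in the ground truth (a class absent from both truth and
  prediction does not dilute the average);
* the per-phase error rate is the fraction of that phase's segments
  classified elsewhere; the average error rate is the unweighted mean
  over phases present; the total error rate is the pooled fraction of
  misclassified segments (1 - accuracy).  Per-phase averaging and
  pooled counting give different numbers on imbalanced sets, which is
  why both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import N_PHASES, PHASES

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "prf_scores",
    "error_rates",
    "cohen_kappa",
    "timeline_report",
    "evaluate_predictions",
]

EXTRA = 8


def _as_labels(x: Sequence[int]) -> np.ndarray:
    arr = np.asarray(x, dtype=int)
    if arr.size and (arr.min() < 1 or arr.max() > N_PHASES):
        raise ValueError(f"labels must be in 1..{N_PHASES}")
    return arr


def confusion_matrix(y_true: Sequence[int], y_pred: Sequence[int]) -> np.ndarray:
    """8x8 count matrix; entry (p-1, q-1) = truth-p segments predicted q."""
    t = _as_labels(y_true)
    p = _as_labels(y_pred)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} vs {len(p)}")
    cm = np.zeros((N_PHASES, N_PHASES), dtype=int)
    for a, b in zip(t, p):
        cm[a - 1, b - 1] += 1
    return cm


def prf_scores(confusion: np.ndarray) -> dict:
    """Per-class precision/recall/F1 and macro-F1 from a confusion matrix.

    A class with no predicted samples gets precision 0, one with no true
    samples gets recall 0; such degenerate scores are flagged.  Macro-F1
    averages over classes present in the truth.
    """
    cm = np.asarray(confusion, dtype=float)
    n = cm.shape[0]
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp

    precision = np.zeros(n)
    recall = np.zeros(n)
    f1 = np.zeros(n)
    degenerate: list[int] = []
    for c in range(n):
        if tp[c] + fp[c] > 0:
            precision[c] = tp[c] / (tp[c] + fp[c])
        else:
            degenerate.append(c + 1)
        if tp[c] + fn[c] > 0:
            recall[c] = tp[c] / (tp[c] + fn[c])
        elif c + 1 not in degenerate:
            degenerate.append(c + 1)
        if precision[c] + recall[c] > 0:
            f1[c] = 2 * precision[c] * recall[c] / (precision[c] + recall[c])

    present = cm.sum(axis=1) > 0
    macro_f1 = float(f1[present].mean()) if present.any() else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "macro_f1": macro_f1,
        "present": present,
        "degenerate_classes": degenerate,
    }


def error_rates(confusion: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(per_phase, average, total) error rates from a confusion matrix.

    per_phase[p-1] = 1 - cm[p,p]/rowsum(p) for phases with truth
    samples (NaN otherwise); average = mean over those phases; total =
    1 - trace/sum.
    """
    cm = np.asarray(confusion, dtype=float)
    rowsums = cm.sum(axis=1)
    per_phase = np.full(cm.shape[0], np.nan)
    mask = rowsums > 0
    per_phase[mask] = 1.0 - np.diag(cm)[mask] / rowsums[mask]
    average = float(np.nanmean(per_phase)) if mask.any() else 0.0
    total = float(1.0 - np.trace(cm) / cm.sum()) if cm.sum() > 0 else 0.0
    return per_phase, average, total


def cohen_kappa(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Chance-corrected agreement between two annotations of the same
    segments: kappa = (p_o - p_e) / (1 - p_e)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("need at least one label")
    n = len(a)
    p_o = float(np.mean(a == b))
    cats = np.union1d(a, b)
    p_e = float(sum((np.mean(a == c)) * (np.mean(b == c)) for c in cats))
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def timeline_report(
    truth_timeline: Sequence[int], predicted: Sequence[int]
) -> tuple[list[tuple[int, int, int]], int]:
    """Paired (index, truth, predicted) triples plus a disruption count.

    A disruption is a predicted backward jump in the monotone surgical
    progression: a position whose predicted non-extra phase is strictly
    lower than the maximum non-extra phase already predicted earlier in
    the video.  Extra-phase predictions are ignored by the rule, since
    conversation legitimately interleaves with any phase.
    """
    t = _as_labels(truth_timeline)
    p = _as_labels(predicted)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} vs {len(p)}")
    triples = [(i, int(a), int(b)) for i, (a, b) in enumerate(zip(t, p))]
    disruptions = 0
    high = 0
    for b in p:
        if b == EXTRA:
            continue
        if b < high:
            disruptions += 1
        high = max(high, int(b))
    return triples, disruptions


@dataclass
class EvalReport:
    """Bundle of all evaluation outputs for one prediction set."""

    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    accuracy: float
    per_phase_error: np.ndarray
    average_error: float
    total_error: float
    n_segments: int
    degenerate_classes: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "error_rate": self.per_phase_error,
            },
            index=[f"phase_{p}" if p < 8 else "extra" for p in PHASES],
        )

    def confusion_percent(self) -> np.ndarray:
        """Row-normalized confusion in percent (rows without truth -> 0)."""
        cm = self.confusion.astype(float)
        rowsums = cm.sum(axis=1, keepdims=True)
        rowsums[rowsums == 0] = 1.0
        return 100.0 * cm / rowsums


def evaluate_predictions(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> EvalReport:
    cm = confusion_matrix(y_true, y_pred)
    scores = prf_scores(cm)
    per_phase, average, total = error_rates(cm)
    n = int(cm.sum())
    accuracy = float(np.trace(cm) / n) if n else 0.0
    return EvalReport(
        confusion=cm,
        precision=scores["precision"],
        recall=scores["recall"],
        f1=scores["f1"],
        macro_f1=scores["macro_f1"],
        accuracy=accuracy,
        per_phase_error=per_phase,
        average_error=average,
        total_error=total,
        n_segments=n,
        degenerate_classes=scores["degenerate_classes"],
    )
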