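"""Threshold filtering of annotated calls and confusion/ROC metrics.

Filtering deletions on DHFFC < 0.7 (or duplications on DHBFC > 1.3) can only
remove calls, so it can only improve precision, never recall.  Missing
annotations always pass a filter: absence of depth evidence must not delete a
call.  ROC curves sweep sensitivity/specificity over all distinct score
thresholds; the trapezoidal AUC equals the pairwise rank statistic with ties
counted one half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .sv_annotate import SVRecord

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class LabeledScore:
    """A fold-change value with its truth class (True = event present)."""

    score: float
    label: bool


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Precision, recall, F1 and FDR from call counts, rounded to 3 decimals."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp + fp == 0:
        raise UndefinedMetricError("precision/fdr undefined: tp + fp == 0")
    if tp + fn == 0:
        raise UndefinedMetricError("recall undefined: tp + fn == 0")
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    if precision + recall == 0:
        raise UndefinedMetricError("f1 undefined: precision + recall == 0")
    f1 = 2 * precision * recall / (precision + recall)
    fdr = fp / (tp + fp)
    return {
        "precision": round(precision, 3),
        "recall": round(recall, 3),
        "f1": round(f1, 3),
        "fdr": round(fdr, 3),
    }


_COMPARATORS = {
    "<": lambda v, c: v < c,
    ">": lambda v, c: v > c,
    "<=": lambda v, c: v <= c,
    ">=": lambda v, c: v >= c,
}


def apply_threshold_filter(
    records: Iterable[SVRecord],
    svtype: str,
    field: str,
    comparator: str,
    cutoff: float,
) -> list[SVRecord]:
    """Retain records of ``svtype`` whose fold-change passes the comparison.

    Records of other SV types are always retained, as are records whose
    annotation is missing (no depth evidence cannot reject a call).  The
    published cutoffs use strict inequalities: DHFFC < 0.7 for deletions,
    DHBFC > 1.3 for duplications.
    """
    field = field.upper()
    if field not in ("DHBFC", "DHFFC"):
        raise ValueError(f"unknown fold-change field {field!r}")
    if comparator not in _COMPARATORS:
        raise ValueError(f"unknown comparator {comparator!r}")
    cmp = _COMPARATORS[comparator]
    attr = field.lower()
    retained = []
    for rec in records:
        if rec.svtype != svtype:
            retained.append(rec)
            continue
        value = getattr(rec.annotations, attr)
        if value is None or cmp(value, cutoff):
            retained.append(rec)
    return retained


def roc_and_auc(
    scores: Sequence[LabeledScore],
    direction: str = "lower",
) -> tuple[list[tuple[float, float, float]], float]:
    """ROC points (threshold, sensitivity, specificity) and trapezoidal AUC.

    ``direction`` says which way the score indicates an event: "lower" (a
    deletion's DHFFC sits below the null class) or "higher" (a duplication's
    DHBFC sits above it).  Tied scores occupy a single threshold step, so the
    trapezoidal AUC equals the pairwise rank statistic with ties counted 1/2.
    """
    if direction not in ("lower", "higher"):
        raise ValueError(f"direction must be 'lower' or 'higher', got {direction!r}")
    labels = np.array([s.label for s in scores], dtype=bool)
    values = np.array([s.score for s in scores], dtype=float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one score of each truth class")
    # orient so that a larger oriented score means "more event-like"
    oriented = -values if direction == "lower" else values
    order = np.argsort(-oriented, kind="stable")
    oriented = oriented[order]
    labels = labels[order]
    points: list[tuple[float, float, float]] = []
    xs = [0.0]  # false-positive rate = 1 - specificity
    ys = [0.0]  # sensitivity
    tp = fp = 0
    i = 0
    n = labels.size
    while i < n:
        j = i
        while j < n and oriented[j] == oriented[i]:
            tp += int(labels[j])
            fp += int(not labels[j])
            j += 1
        sens = tp / n_pos
        spec = 1 - fp / n_neg
        raw_threshold = -oriented[i] if direction == "lower" else oriented[i]
        points.append((float(raw_threshold), sens, spec))
        xs.append(fp / n_neg)
        ys.append(sens)
        i = j
    auc = float(np.trapezoid(ys, xs))
    return points, auc


def summarize_filter_effect(
    before: ConfusionCounts, after: ConfusionCounts
) -> dict[str, int]:
    """Percent of false positives removed and true positives retained.

    Matches the headline arithmetic: removing (83-32)/83 = 61% of false
    positives while retaining 1483/1496 = 99% of true positives.
    """
    if after.tp > before.tp or after.fp > before.fp:
        raise ValueError("filtering cannot increase tp or fp")
    if before.fp == 0:
        raise UndefinedMetricError("fp_removed undefined: no false positives before filtering")
    fp_removed = (before.fp - after.fp) / before.fp
    tp_retained = after.tp / before.tp if before.tp else 1.0
    return {
        "fp_removed_pct": round(fp_removed * 100),
        "tp_retained_pct": round(tp_retained * 100),
    }
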