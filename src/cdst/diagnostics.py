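"""Diagnostic-accuracy statistics for a screener validated against a gold
standard.

Given record-level data (CDST total score + gold-standard depression label
per child) this module computes, for any cutoff, the 2x2 confusion matrix
and its operating characteristics (sensitivity, specificity, PPV, NPV,
balanced accuracy), the full empirical ROC curve over the integer score
range, and the cutoff that maximises balanced accuracy.

Two different "AUC" notions are deliberately kept apart:

* per-cutoff balanced accuracy ``(Se + Sp) / 2`` — the area of the
  single-point ROC polygon for that cutoff, which is what per-cutoff "AUC"
  columns in screening validation tables report; and
* the empirical trapezoidal AUC of the full threshold sweep, which equals
  the tie-adjusted Mann-Whitney pair-counting statistic
  ``P(S+ > S-) + 0.5 * P(S+ = S-)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .instrument import ITEM_COLUMNS, MAX_SCORE

LABEL_COLUMN = "gold_standard_depressed"
SCORE_COLUMN = "total_score"


class CohortError(ValueError):
    """Raised for cohorts the requested statistic is undefined on."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 screen-vs-gold-standard counts at one cutoff."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class AccuracyStats:
    """Operating characteristics derived from a confusion matrix.

    Ratios with a zero denominator are ``None`` (an explicit "undefined"
    marker), never 0 and never an exception: degenerate cells occur
    routinely at the extremes of a threshold sweep.
    """

    counts: ConfusionMatrix
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    balanced_accuracy: Optional[float]


@dataclass(frozen=True)
class OperatingTable:
    """Per-cutoff operating characteristics over a contiguous cutoff range."""

    rows: tuple[tuple[int, AccuracyStats], ...]

    def __iter__(self) -> Iterator[tuple[int, AccuracyStats]]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def stats_at(self, cutoff: int) -> AccuracyStats:
        for c, stats in self.rows:
            if c == cutoff:
                return stats
        raise KeyError(cutoff)

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for cutoff, s in self.rows:
            cm = s.counts
            records.append(
                dict(cutoff=cutoff, tp=cm.tp, fp=cm.fp, fn=cm.fn, tn=cm.tn,
                     sensitivity=s.sensitivity, specificity=s.specificity,
                     ppv=s.ppv, npv=s.npv,
                     balanced_accuracy=s.balanced_accuracy)
            )
        return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC curve over all integer thresholds (max+1 down to 0).

    ``fpr`` / ``tpr`` run from (0, 0) to (1, 1); ``auc`` is the trapezoidal
    area, identical to the tie-adjusted pair-counting statistic.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


RecordsLike = Union[pd.DataFrame, tuple[Sequence[int], Sequence[bool]]]


def cohort_scores(records: pd.DataFrame) -> np.ndarray:
    """CDST totals per row: an existing ``total_score`` column, else the
    sum of the 11 item columns."""
    if SCORE_COLUMN in records.columns:
        return records[SCORE_COLUMN].to_numpy(dtype=int)
    missing = [c for c in ITEM_COLUMNS if c not in records.columns]
    if missing:
        raise CohortError(f"cohort lacks item columns: {', '.join(missing)}")
    return records[list(ITEM_COLUMNS)].to_numpy(dtype=int).sum(axis=1)


def _scores_labels(records: RecordsLike) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        if len(records) == 0:
            raise CohortError("empty cohort")
        if LABEL_COLUMN not in records.columns:
            raise CohortError(f"cohort lacks '{LABEL_COLUMN}' column")
        scores = cohort_scores(records)
        labels = records[LABEL_COLUMN].astype(bool).to_numpy()
    else:
        scores_seq, labels_seq = records
        scores = np.asarray(scores_seq, dtype=int)
        labels = np.asarray(labels_seq, dtype=bool)
        if scores.size == 0:
            raise CohortError("empty cohort")
        if scores.shape != labels.shape:
            raise CohortError("scores and labels differ in length")
    if scores.min() < 0 or scores.max() > MAX_SCORE:
        raise CohortError("scores outside the instrument range [0, 33]")
    return scores, labels


def confusion_at_cutoff(records: RecordsLike, cutoff: int) -> ConfusionMatrix:
    """Cross-classify screen result (score >= cutoff) against the gold
    standard."""
    scores, labels = _scores_labels(records)
    screen_pos = scores >= cutoff
    return ConfusionMatrix(
        tp=int(np.sum(screen_pos & labels)),
        fp=int(np.sum(screen_pos & ~labels)),
        fn=int(np.sum(~screen_pos & labels)),
        tn=int(np.sum(~screen_pos & ~labels)),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def accuracy_stats(cm: ConfusionMatrix) -> AccuracyStats:
    """Sensitivity, specificity, predictive values and balanced accuracy.

    Balanced accuracy is reported only when both sensitivity and
    specificity are defined.
    """
    se = _ratio(cm.tp, cm.tp + cm.fn)
    sp = _ratio(cm.tn, cm.tn + cm.fp)
    ba = (se + sp) / 2 if se is not None and sp is not None else None
    return AccuracyStats(
        counts=cm,
        sensitivity=se,
        specificity=sp,
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        balanced_accuracy=ba,
    )


def operating_table(records: RecordsLike, cutoff_min: int = 4,
                    cutoff_max: int = 10) -> OperatingTable:
    """One row of operating characteristics per cutoff in the range."""
    if cutoff_min > cutoff_max:
        raise ValueError("cutoff_min must not exceed cutoff_max")
    scores, labels = _scores_labels(records)
    rows = []
    for cutoff in range(cutoff_min, cutoff_max + 1):
        cm = confusion_at_cutoff((scores, labels), cutoff)
        rows.append((cutoff, accuracy_stats(cm)))
    return OperatingTable(rows=tuple(rows))


def roc_curve(records: RecordsLike) -> ROCCurve:
    """Empirical ROC over thresholds 34 down to 0.

    Point ``i`` is (FPR, TPR) at threshold ``t_i``, where a subject is
    called positive when ``score >= t_i``.  The trapezoidal area equals the
    Mann-Whitney statistic with ties weighted one-half; with integer
    scores and a full sweep the curve is exact, not interpolated.
    """
    scores, labels = _scores_labels(records)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise CohortError("ROC requires at least one positive and one negative")
    thresholds = np.arange(MAX_SCORE + 1, -1, -1)
    pos_scores = scores[labels]
    neg_scores = scores[~labels]
    tpr = (pos_scores[None, :] >= thresholds[:, None]).sum(axis=1) / n_pos
    fpr = (neg_scores[None, :] >= thresholds[:, None]).sum(axis=1) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr.astype(float), tpr=tpr.astype(float),
                    thresholds=thresholds, auc=auc)


def optimal_cutoff(table: OperatingTable) -> int:
    """Cutoff maximising balanced accuracy; ties go to the larger cutoff
    (the more specific screen, which burdens referral services less)."""
    if len(table) == 0:
        raise ValueError("empty operating table")
    best_cutoff: Optional[int] = None
    best_ba = -np.inf
    for cutoff, stats in table:
        ba = stats.balanced_accuracy
        if ba is None:
            continue
        if ba >= best_ba:
            best_ba = ba
            best_cutoff = cutoff
    if best_cutoff is None:
        raise CohortError("no cutoff with defined balanced accuracy")
    return best_cutoff


def exceedance_counts(records: RecordsLike, cutoff_min: int,
                      cutoff_max: int) -> tuple[list[int], list[int]]:
    """Per-group counts of scores >= k for each cutoff k in the range.

    Returns (positive-group counts, negative-group counts); the integer
    backbone of a cutoff table such as a published Se/Sp-by-cutoff table.
    """
    scores, labels = _scores_labels(records)
    pos = scores[labels]
    neg = scores[~labels]
    ks = range(cutoff_min, cutoff_max + 1)
    return ([int(np.sum(pos >= k)) for k in ks],
            [int(np.sum(neg >= k)) for k in ks])
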