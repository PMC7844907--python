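"""Invert display-rounded percentages back to the underlying integer counts.

Published validation tables report sensitivity, specificity, predictive
values and subgroup prevalences as percentages rounded to one decimal.
Because every such percentage is ``100 * k / n`` for an integer numerator
``k`` out of a known denominator ``n``, rounding can be inverted: the set
of numerators consistent with a printed value is computable exactly, and
the joint system of all cells in a table (plus the monotonicity that
exceedance counts must satisfy across cutoffs) usually pins down a unique
solution.  This is the same arithmetic that powers GRIM-style consistency
checks of published tables, used constructively here: the recovered counts
become an exact record-level fixture for the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

from .tables import (
    CUTOFF_TABLE,
    N_CHILDREN,
    OVERALL_PREVALENCE_PCT,
    PREVALENCE_PARTITIONS,
    PrintedCutoffRow,
)

#: Absolute slack around a printed value: half an ulp of the printed
#: precision plus an epsilon guarding against binary-float edge cases.
_EPS = 1e-9


class ReconstructionError(ValueError):
    """Base class for failures to invert a printed table."""


class InconsistentTableError(ReconstructionError):
    """No integer counts reproduce the printed cells."""


class AmbiguousTableError(ReconstructionError):
    """More than one set of integer counts reproduces the printed cells."""


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (the convention of printed tables), e.g.
    99.606 -> 99.6 and 0.125 -> 0.13 at two decimals."""
    q = Decimal(str(x)).quantize(Decimal(1).scaleb(-decimals),
                                 rounding=ROUND_HALF_UP)
    return float(q)


def invert_rounded_percent(n: int, reported_pct: float,
                           decimals: int = 1) -> list[int]:
    """All numerators ``k`` in [0, n] whose percentage rounds to the report.

    Returns the (possibly empty, possibly multi-element) sorted list of
    ``k`` with ``|100 k / n - reported_pct| <= 0.5 * 10**-decimals + eps``.
    An empty list flags an internally inconsistent report; more than one
    element flags ambiguity that only joint constraints can resolve.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= reported_pct <= 100.0:
        raise ValueError("reported_pct must be in [0, 100]")
    tol = 0.5 * 10.0 ** (-decimals) + _EPS
    return [k for k in range(n + 1) if abs(100.0 * k / n - reported_pct) <= tol]


@dataclass(frozen=True)
class ExceedanceProfile:
    """Exceedance counts TP(k), FP(k) for a contiguous cutoff range.

    ``tp[i]`` is the number of gold-standard positives scoring at or above
    ``cutoffs[i]``; ``fp[i]`` likewise among negatives.  Both sequences are
    non-increasing in the cutoff.
    """

    n_pos: int
    n_neg: int
    cutoffs: tuple[int, ...]
    tp: tuple[int, ...]
    fp: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.cutoffs) == len(self.tp) == len(self.fp)):
            raise ValueError("cutoffs, tp and fp must have equal length")
        if list(self.cutoffs) != list(range(self.cutoffs[0],
                                            self.cutoffs[0] + len(self.cutoffs))):
            raise ValueError("cutoffs must be contiguous and increasing")
        for counts, bound, name in ((self.tp, self.n_pos, "tp"),
                                    (self.fp, self.n_neg, "fp")):
            for c in counts:
                if not 0 <= c <= bound:
                    raise ValueError(f"{name} count {c} outside [0, {bound}]")
            if any(a < b for a, b in zip(counts, counts[1:])):
                raise ValueError(f"{name} exceedance counts must be non-increasing")

    def count_pos_ge(self, cutoff: int) -> int:
        return self.tp[self.cutoffs.index(cutoff)]

    def count_neg_ge(self, cutoff: int) -> int:
        return self.fp[self.cutoffs.index(cutoff)]

    def to_dict(self) -> dict:
        return {
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "cutoffs": list(self.cutoffs),
            "tp": list(self.tp),
            "fp": list(self.fp),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExceedanceProfile":
        return cls(n_pos=int(d["n_pos"]), n_neg=int(d["n_neg"]),
                   cutoffs=tuple(int(c) for c in d["cutoffs"]),
                   tp=tuple(int(c) for c in d["tp"]),
                   fp=tuple(int(c) for c in d["fp"]))


@dataclass(frozen=True)
class ScoreHistogram:
    """Binned score counts for one gold-standard group.

    Bins are ``"<kmin"``, one bin per integer score in [kmin, kmax-1], and
    ``">=kmax"``; this is exactly the resolution a cutoff table over
    [kmin, kmax] determines.
    """

    group: str
    kmin: int
    kmax: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        expected = self.bin_labels(self.kmin, self.kmax)
        if list(self.counts) != expected:
            raise ValueError(f"bins must be exactly {expected}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative bin count")

    @staticmethod
    def bin_labels(kmin: int, kmax: int) -> list[str]:
        return [f"<{kmin}", *[str(k) for k in range(kmin, kmax)], f">={kmax}"]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {"group": self.group, "kmin": self.kmin, "kmax": self.kmax,
                "counts": dict(self.counts)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoreHistogram":
        return cls(group=str(d["group"]), kmin=int(d["kmin"]),
                   kmax=int(d["kmax"]),
                   counts={str(k): int(v) for k, v in d["counts"].items()})


def _row_candidates(n_pos: int, n_neg: int, row: PrintedCutoffRow,
                    decimals: int = 1) -> list[tuple[int, int]]:
    """(TP, FP) pairs jointly consistent with every printed cell of a row."""
    tol_pct = 0.5 * 10.0 ** (-decimals) + _EPS
    tol_auc = 0.5e-3 + _EPS
    tp_cands = invert_rounded_percent(n_pos, row.sensitivity_pct, decimals)
    fp_cands = [n_neg - m
                for m in invert_rounded_percent(n_neg, row.specificity_pct, decimals)]
    pairs = []
    for tp, fp in product(tp_cands, fp_cands):
        fn, tn = n_pos - tp, n_neg - fp
        if tp + fp == 0 or tn + fn == 0:
            continue
        ppv = 100.0 * tp / (tp + fp)
        npv = 100.0 * tn / (tn + fn)
        ba = (tp / n_pos + tn / n_neg) / 2.0
        if (abs(ppv - row.ppv_pct) <= tol_pct
                and abs(npv - row.npv_pct) <= tol_pct
                and abs(ba - row.auc) <= tol_auc):
            pairs.append((tp, fp))
    return pairs


def reconstruct_cutoff_table(n_pos: int, n_neg: int,
                             rows: Sequence[PrintedCutoffRow] = CUTOFF_TABLE,
                             decimals: int = 1) -> ExceedanceProfile:
    """Recover the unique exceedance profile behind a printed cutoff table.

    Each row's (TP, FP) must jointly re-round to the printed sensitivity,
    specificity, PPV, NPV and balanced-accuracy cells, and TP and FP must
    be non-increasing across cutoffs.  Raises
    :class:`InconsistentTableError` (naming the first offending cutoff) if
    no assignment survives, :class:`AmbiguousTableError` if several do.
    """
    rows = sorted(rows, key=lambda r: r.cutoff)
    cutoffs = [r.cutoff for r in rows]
    if cutoffs != list(range(cutoffs[0], cutoffs[0] + len(cutoffs))):
        raise ValueError("rows must cover a contiguous cutoff range")
    per_row = []
    for row in rows:
        cands = _row_candidates(n_pos, n_neg, row, decimals)
        if not cands:
            raise InconsistentTableError(
                f"no (TP, FP) pair reproduces the printed cells at cutoff "
                f"{row.cutoff}")
        per_row.append(cands)

    solutions: list[tuple[tuple[int, int], ...]] = []

    def extend(i: int, acc: list[tuple[int, int]]) -> None:
        if i == len(per_row):
            solutions.append(tuple(acc))
            return
        for tp, fp in per_row[i]:
            if acc and (tp > acc[-1][0] or fp > acc[-1][1]):
                continue  # exceedance counts cannot rise with the cutoff
            acc.append((tp, fp))
            extend(i + 1, acc)
            acc.pop()

    extend(0, [])
    if not solutions:
        raise InconsistentTableError(
            "per-row candidates exist but none satisfy exceedance "
            "monotonicity across cutoffs")
    if len(solutions) > 1:
        diff = next(i for i in range(len(rows))
                    if len({s[i] for s in solutions}) > 1)
        raise AmbiguousTableError(
            f"{len(solutions)} profiles reproduce the table; first ambiguous "
            f"cutoff is {rows[diff].cutoff}")
    sol = solutions[0]
    return ExceedanceProfile(
        n_pos=n_pos, n_neg=n_neg, cutoffs=tuple(cutoffs),
        tp=tuple(tp for tp, _ in sol), fp=tuple(fp for _, fp in sol))


def reconstruct_prevalence_partitions(
    overall_n: int = N_CHILDREN,
    overall_pct: float = OVERALL_PREVALENCE_PCT,
    partitions: Mapping[str, Iterable[tuple[str, int, float]]] = PREVALENCE_PARTITIONS,
    decimals: int = 1,
) -> tuple[int, dict[str, dict[str, int]]]:
    """Recover subgroup positive counts from printed prevalences.

    Every partition of the cohort must yield per-subgroup counts that (a)
    re-round to the printed prevalence and (b) sum to the same overall
    positive count, itself consistent with the printed overall prevalence.
    Returns ``(overall_positives, {partition: {label: positives}})``.
    """
    overall_cands = set(invert_rounded_percent(overall_n, overall_pct, decimals))
    if not overall_cands:
        raise InconsistentTableError(
            "no overall positive count matches the printed prevalence")
    results: dict[str, dict[str, int]] = {}
    feasible_totals: Optional[set[int]] = None
    partition_solutions: dict[str, dict[int, tuple[int, ...]]] = {}
    for name, spec_rows in partitions.items():
        spec_rows = list(spec_rows)
        sizes = [n for _, n, _ in spec_rows]
        if sum(sizes) != overall_n:
            raise ValueError(
                f"partition '{name}' sizes sum to {sum(sizes)}, not {overall_n}")
        cand_sets = []
        for label, n, pct in spec_rows:
            cands = invert_rounded_percent(n, pct, decimals)
            if not cands:
                raise InconsistentTableError(
                    f"no count matches the printed prevalence for "
                    f"'{label}' in partition '{name}'")
            cand_sets.append(cands)
        by_total: dict[int, list[tuple[int, ...]]] = {}
        for combo in product(*cand_sets):
            t = sum(combo)
            if t in overall_cands:
                by_total.setdefault(t, []).append(combo)
        if not by_total:
            raise InconsistentTableError(
                f"partition '{name}' admits no combination summing to a "
                f"feasible overall positive count")
        for t, combos in by_total.items():
            if len(combos) > 1:
                raise AmbiguousTableError(
                    f"partition '{name}' admits {len(combos)} combinations "
                    f"summing to {t}")
        partition_solutions[name] = {t: combos[0]
                                     for t, combos in by_total.items()}
        totals = set(by_total)
        feasible_totals = totals if feasible_totals is None else feasible_totals & totals
    if not feasible_totals:
        raise InconsistentTableError(
            "partitions do not agree on any overall positive count")
    if len(feasible_totals) > 1:
        raise AmbiguousTableError(
            f"overall positive count ambiguous: {sorted(feasible_totals)}")
    total = feasible_totals.pop()
    for name, spec_rows in partitions.items():
        combo = partition_solutions[name][total]
        results[name] = {label: k
                         for (label, _, _), k in zip(list(spec_rows), combo)}
    return total, results


def histogram_from_exceedance(profile: ExceedanceProfile
                              ) -> tuple[ScoreHistogram, ScoreHistogram]:
    """Difference an exceedance profile into per-group score histograms.

    Bin ``"<kmin"`` holds everyone below the first cutoff, interior bins
    hold exact scores, and ``">=kmax"`` holds the top exceedance count.
    """
    kmin, kmax = profile.cutoffs[0], profile.cutoffs[-1]

    def bins(counts: Sequence[int], group_n: int, group: str) -> ScoreHistogram:
        labels = ScoreHistogram.bin_labels(kmin, kmax)
        values = [group_n - counts[0],
                  *[counts[i] - counts[i + 1] for i in range(len(counts) - 1)],
                  counts[-1]]
        if any(v < 0 for v in values):
            raise ReconstructionError("non-monotone profile: negative bin count")
        return ScoreHistogram(group=group, kmin=kmin, kmax=kmax,
                              counts=dict(zip(labels, values)))

    return (bins(profile.tp, profile.n_pos, "positive"),
            bins(profile.fp, profile.n_neg, "negative"))


def reconstruct_study() -> dict:
    """One-call reconstruction of the full study skeleton.

    Returns a dict with the overall positive count, the per-partition
    positive counts, the cutoff-table exceedance profile and the two score
    histograms, all recovered from the printed tables.
    """
    n_pos, partitions = reconstruct_prevalence_partitions()
    profile = reconstruct_cutoff_table(n_pos=n_pos, n_neg=N_CHILDREN - n_pos)
    pos_hist, neg_hist = histogram_from_exceedance(profile)
    return {
        "n_total": N_CHILDREN,
        "n_pos": n_pos,
        "n_neg": N_CHILDREN - n_pos,
        "partition_positives": partitions,
        "profile": profile,
        "pos_histogram": pos_hist,
        "neg_histogram": neg_hist,
    }
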