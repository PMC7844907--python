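"""Seeded generation of record-level validation cohorts.

The study's raw data were never deposited; what the publication fixes is
the integer skeleton recovered by :mod:`cdst.reconstruction` — group sizes,
per-group score histograms at the resolution of the cutoff table, and the
demographic margins (plus the province/age/sex cross-classifications with
depression status).  :func:`generate_cohort` turns that skeleton into a
full cohort of child records: every constrained count is matched *exactly*
(margins are allocated as fixed integer counts and shuffled, not sampled),
and only the unconstrained detail — placement of scores inside the open
"<4" and ">=10" bins, item-level decomposition of each total, exact age
within an age band, pairing of unlinked demographics — uses the seed.

By construction, every statistic the cutoff table determines (all
operating characteristics at cutoffs 4-10, subgroup prevalences) is
identical across seeds; re-running with the same seed reproduces the
cohort byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd

from .instrument import ITEM_COLUMNS, MAX_ITEM_VALUE, MAX_SCORE, N_ITEMS
from .reconstruction import ScoreHistogram, reconstruct_study
from .tables import AGE_BAND_YEARS, demographic_margins

#: Within-band age weights for the calibrated age mode, chosen so the
#: cohort mean age lands near the published mean 12 (SD 1.9) instead of
#: the uniform-within-band mean 11.7.
_CALIBRATED_AGE_WEIGHTS = {
    "7-9": {7: 0.10, 8: 0.20, 9: 0.70},
    "10-12": {10: 0.15, 11: 0.25, 12: 0.60},
    "13-14": {13: 0.55, 14: 0.45},
}

#: Facility layout: each province hosts 2 urban and 3 rural study sites.
_FACILITIES_PER_PROVINCE = {"urban": 2, "rural": 3}


class CohortSpecError(ValueError):
    """Raised when a cohort specification is internally inconsistent."""


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of a synthetic validation cohort.

    ``margins`` gives, per categorical variable, level counts summing to
    ``n_pos + n_neg``.  ``joint_positive`` gives, for the variables whose
    cross-classification with depression is known (province, age band,
    sex), the positive count per level; other variables are assigned
    independently of depression status given their margins.
    """

    n_pos: int
    n_neg: int
    pos_histogram: ScoreHistogram
    neg_histogram: ScoreHistogram
    margins: dict[str, dict[str, int]]
    joint_positive: dict[str, dict[str, int]] = field(default_factory=dict)
    low_bin_rule: str = "uniform"          # scores below kmin
    high_bin_rule: str = "geometric"       # scores at/above kmax
    high_bin_ratio: float = 0.6
    age_mode: str = "uniform"              # or "calibrated"
    with_facilities: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.n_pos + self.n_neg
        if self.pos_histogram.total != self.n_pos:
            raise CohortSpecError(
                f"positive histogram totals {self.pos_histogram.total}, "
                f"expected {self.n_pos}")
        if self.neg_histogram.total != self.n_neg:
            raise CohortSpecError(
                f"negative histogram totals {self.neg_histogram.total}, "
                f"expected {self.n_neg}")
        for var, levels in self.margins.items():
            if sum(levels.values()) != n:
                raise CohortSpecError(
                    f"margin '{var}' sums to {sum(levels.values())}, "
                    f"expected {n}")
        for var, levels in self.joint_positive.items():
            if var not in self.margins:
                raise CohortSpecError(f"joint margin '{var}' has no marginal")
            if sum(levels.values()) != self.n_pos:
                raise CohortSpecError(
                    f"joint margin '{var}' sums to {sum(levels.values())}, "
                    f"expected n_pos={self.n_pos}")
            for level, k in levels.items():
                if level not in self.margins[var]:
                    raise CohortSpecError(
                        f"joint margin '{var}' has unknown level '{level}'")
                if k > self.margins[var][level]:
                    raise CohortSpecError(
                        f"joint margin '{var}'='{level}' positives {k} exceed "
                        f"the marginal count {self.margins[var][level]}")


def study_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default cohort specification: the reconstructed study skeleton.

    296 children, 42 interview-positive, score histograms and
    province/age/sex cross-classifications recovered from the printed
    tables, remaining demographic margins from the published demographics
    table.
    """
    study = reconstruct_study()
    spec = CohortSpec(
        n_pos=study["n_pos"],
        n_neg=study["n_neg"],
        pos_histogram=study["pos_histogram"],
        neg_histogram=study["neg_histogram"],
        margins=demographic_margins(study["n_total"]),
        joint_positive=study["partition_positives"],
        seed=seed,
    )
    return replace(spec, **overrides) if overrides else spec


@lru_cache(maxsize=None)
def _compositions(parts: int, total: int) -> int:
    """Number of ways to write ``total`` as ``parts`` ordered values in
    {0..3}."""
    if total < 0 or total > parts * MAX_ITEM_VALUE:
        return 0
    if parts == 0:
        return 1 if total == 0 else 0
    return sum(_compositions(parts - 1, total - v)
               for v in range(MAX_ITEM_VALUE + 1))


def decompose_score(total: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Split a CDST total into 11 item values uniformly over all valid
    compositions (each item in {0..3}), by sequential conditional sampling
    with exact composition counts."""
    if not 0 <= total <= MAX_SCORE:
        raise ValueError(f"total {total} outside [0, {MAX_SCORE}]")
    values = []
    remaining = total
    for i in range(N_ITEMS):
        parts_left = N_ITEMS - i - 1
        weights = np.array(
            [_compositions(parts_left, remaining - v)
             for v in range(MAX_ITEM_VALUE + 1)], dtype=float)
        v = int(rng.choice(MAX_ITEM_VALUE + 1, p=weights / weights.sum()))
        values.append(v)
        remaining -= v
    return tuple(values)


def _expand_histogram(hist: ScoreHistogram, rule_low: str, rule_high: str,
                      ratio: float, rng: np.random.Generator) -> np.ndarray:
    """Materialise the binned histogram as individual integer scores."""
    scores: list[int] = []
    for label, count in hist.counts.items():
        if count == 0:
            continue
        if label.startswith("<"):
            lo_vals = np.arange(0, hist.kmin)
            if rule_low == "uniform":
                drawn = rng.choice(lo_vals, size=count)
            else:
                raise CohortSpecError(f"unknown low_bin_rule '{rule_low}'")
            scores.extend(int(v) for v in drawn)
        elif label.startswith(">="):
            hi_vals = np.arange(hist.kmax, MAX_SCORE + 1)
            if rule_high == "geometric":
                w = ratio ** (hi_vals - hist.kmax)
                drawn = rng.choice(hi_vals, size=count, p=w / w.sum())
            elif rule_high == "uniform":
                drawn = rng.choice(hi_vals, size=count)
            else:
                raise CohortSpecError(f"unknown high_bin_rule '{rule_high}'")
            scores.extend(int(v) for v in drawn)
        else:
            scores.extend([int(label)] * count)
    return np.array(scores, dtype=int)


def _allocate_levels(counts: dict[str, int], rng: np.random.Generator
                     ) -> np.ndarray:
    """Fixed-count level assignment: repeat each level exactly its count,
    then shuffle."""
    labels = np.array([lv for lv, c in counts.items() for _ in range(c)],
                      dtype=object)
    rng.shuffle(labels)
    return labels


def _ages_from_bands(bands: np.ndarray, mode: str,
                     rng: np.random.Generator) -> np.ndarray:
    ages = np.empty(len(bands), dtype=int)
    for band, years in AGE_BAND_YEARS.items():
        idx = np.flatnonzero(bands == band)
        if len(idx) == 0:
            continue
        if mode == "uniform":
            ages[idx] = rng.choice(list(years), size=len(idx))
        elif mode == "calibrated":
            weights = _CALIBRATED_AGE_WEIGHTS[band]
            vals = np.array(list(weights), dtype=int)
            p = np.array(list(weights.values()))
            ages[idx] = rng.choice(vals, size=len(idx), p=p / p.sum())
        else:
            raise CohortSpecError(f"unknown age_mode '{mode}'")
    return ages


def _facility_ids(provinces: np.ndarray, residences: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Assign each child a study facility in their province matching their
    urban/rural residence (2 urban + 3 rural sites per province)."""
    ids = np.empty(len(provinces), dtype=object)
    for i, (prov, res) in enumerate(zip(provinces, residences)):
        n_sites = _FACILITIES_PER_PROVINCE[res]
        site = int(rng.integers(1, n_sites + 1))
        ids[i] = f"{prov}-{res[0].upper()}{site}"
    return ids


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a record-level cohort realising the specification.

    Returns a DataFrame in the standard cohort schema (one row per child,
    11 item columns, demographics, gold-standard label).  Identical seeds
    give identical frames; any statistic determined by the histograms,
    margins or joint margins is identical across seeds.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    if n == 0:
        raise CohortSpecError("cohort must contain at least one record")

    labels = np.array([True] * spec.n_pos + [False] * spec.n_neg, dtype=bool)
    scores = np.concatenate([
        _expand_histogram(spec.pos_histogram, spec.low_bin_rule,
                          spec.high_bin_rule, spec.high_bin_ratio, rng),
        _expand_histogram(spec.neg_histogram, spec.low_bin_rule,
                          spec.high_bin_rule, spec.high_bin_ratio, rng),
    ])

    columns: dict[str, np.ndarray] = {}
    pos_mask = labels
    # variables with a known depression cross-classification: allocate
    # within each gold-standard group so both margins are exact
    for var, joint in spec.joint_positive.items():
        marginal = spec.margins[var]
        neg_counts = {lv: marginal[lv] - joint.get(lv, 0) for lv in marginal}
        if any(c < 0 for c in neg_counts.values()):
            raise CohortSpecError(f"infeasible joint margin for '{var}'")
        values = np.empty(n, dtype=object)
        values[pos_mask] = _allocate_levels(
            {lv: joint.get(lv, 0) for lv in marginal}, rng)
        values[~pos_mask] = _allocate_levels(neg_counts, rng)
        columns[var] = values
    # remaining variables: exact margins, independent of depression status
    for var, marginal in spec.margins.items():
        if var in spec.joint_positive:
            continue
        columns[var] = _allocate_levels(marginal, rng)

    frame = pd.DataFrame(index=pd.RangeIndex(n))
    if "age_band" in columns:
        frame["age_years"] = _ages_from_bands(columns["age_band"],
                                              spec.age_mode, rng)
    for var in ("sex", "province", "residence", "education", "parents_alive",
                "caregiver", "discloser", "art_months_band"):
        if var in columns:
            frame[var] = columns[var]
    if "viral_suppressed" in columns:
        frame["viral_suppressed"] = columns["viral_suppressed"] == "yes"

    items = np.array([decompose_score(int(s), rng) for s in scores], dtype=int)
    for j, col in enumerate(ITEM_COLUMNS):
        frame[col] = items[:, j]
    frame["gold_standard_depressed"] = labels

    if spec.with_facilities:
        if "province" not in columns or "residence" not in columns:
            raise CohortSpecError(
                "facility assignment needs province and residence margins")
        frame["facility_id"] = _facility_ids(columns["province"],
                                             columns["residence"], rng)

    # shuffle record order so the two groups interleave, then assign ids
    order = rng.permutation(n)
    frame = frame.iloc[order].reset_index(drop=True)
    frame.insert(0, "record_id", [f"C{i + 1:04d}" for i in range(n)])
    return frame
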