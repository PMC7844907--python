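"""Published summary numbers from the CDST validation study.

These printed values — cohort size, per-cutoff operating characteristics,
and subgroup prevalences — are the *inputs* to the reconstruction module,
which inverts their display rounding back to integer counts.  Record-level
data for the study were never deposited, so these tables are the only
quantitative anchor available.
"""

from __future__ import annotations

from typing import NamedTuple


class PrintedCutoffRow(NamedTuple):
    """One row of the published sensitivity/specificity-by-cutoff table.

    Percentages are as printed (one decimal); ``auc`` is the per-cutoff
    balanced accuracy printed as a three-decimal proportion.
    """

    cutoff: int
    sensitivity_pct: float
    specificity_pct: float
    auc: float
    ppv_pct: float
    npv_pct: float


#: Operating characteristics at cutoffs 4-10 (42 interview-positive vs 254
#: interview-negative children once reconstructed).
CUTOFF_TABLE: tuple[PrintedCutoffRow, ...] = (
    PrintedCutoffRow(4, 95.2, 86.6, 0.909, 54.1, 99.1),
    PrintedCutoffRow(5, 92.9, 91.3, 0.921, 63.9, 98.7),
    PrintedCutoffRow(6, 88.1, 96.5, 0.923, 80.4, 98.0),
    PrintedCutoffRow(7, 78.6, 98.0, 0.883, 86.8, 96.5),
    PrintedCutoffRow(8, 73.8, 99.2, 0.865, 93.9, 95.8),
    PrintedCutoffRow(9, 57.1, 99.6, 0.784, 96.0, 93.4),
    PrintedCutoffRow(10, 40.5, 99.6, 0.700, 94.4, 91.0),
)

#: Total participants and overall depression prevalence (%) by clinical
#: interview.
N_CHILDREN = 296
OVERALL_PREVALENCE_PCT = 14.2

#: Subgroup sizes and depression prevalences (%), for the partitions whose
#: cross-classification with depression status is identifiable from the
#: published demographics table.  Each partition's sizes sum to 296.
PREVALENCE_PARTITIONS: dict[str, tuple[tuple[str, int, float], ...]] = {
    "province": (
        ("East", 60, 11.7),
        ("West", 70, 24.3),
        ("Kigali", 57, 15.8),
        ("North", 53, 3.8),
        ("South", 56, 12.5),
    ),
    "age_band": (
        ("7-9", 46, 6.5),
        ("10-12", 114, 9.6),
        ("13-14", 136, 20.6),
    ),
    "sex": (
        ("male", 145, 11.0),
        ("female", 151, 17.2),
    ),
}

#: Demographic margins whose printed counts sum to the full 296.
COUNT_MARGINS: dict[str, dict[str, int]] = {
    "province": {"East": 60, "West": 70, "Kigali": 57, "North": 53, "South": 56},
    "age_band": {"7-9": 46, "10-12": 114, "13-14": 136},
    "sex": {"male": 145, "female": 151},
    "residence": {"urban": 146, "rural": 150},
    "parents_alive": {"both": 277, "one": 19},
    "caregiver": {"parents": 255, "other": 41},
    "art_months_band": {"<24": 27, "25-60": 61, "61-120": 139, "121+": 69},
}

#: Margins published only with counts that do NOT sum to 296 (item
#: non-response); rebuilt from the printed percentages by largest-remainder
#: apportionment over the full cohort.
PERCENT_MARGINS: dict[str, dict[str, float]] = {
    "education": {"primary": 94.2, "secondary": 5.8},
    "discloser": {"parents": 53.3, "parent_with_provider": 42.1, "provider": 4.6},
    "viral_suppressed": {"no": 19.2, "yes": 80.8},
}

#: Ages covered by each age band.
AGE_BAND_YEARS: dict[str, tuple[int, ...]] = {
    "7-9": (7, 8, 9),
    "10-12": (10, 11, 12),
    "13-14": (13, 14),
}


def largest_remainder(percentages: dict[str, float], total: int) -> dict[str, int]:
    """Apportion ``total`` across levels proportionally to percentages.

    Floors every quota, then hands the leftover units to the levels with
    the largest fractional remainders (insertion order breaks ties), so
    counts sum exactly to ``total``.
    """
    quotas = {level: total * pct / 100.0 for level, pct in percentages.items()}
    counts = {level: int(q) for level, q in quotas.items()}
    leftover = total - sum(counts.values())
    by_remainder = sorted(quotas, key=lambda lv: quotas[lv] - counts[lv],
                          reverse=True)
    for level in by_remainder[:leftover]:
        counts[level] += 1
    return counts


def demographic_margins(total: int = N_CHILDREN) -> dict[str, dict[str, int]]:
    """All demographic margins as integer counts summing to ``total``."""
    margins = {var: dict(levels) for var, levels in COUNT_MARGINS.items()}
    for var, pcts in PERCENT_MARGINS.items():
        margins[var] = largest_remainder(pcts, total)
    return margins
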