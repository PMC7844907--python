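"""Prevalence estimation with survey design effects, and subgroup
comparisons.

Point estimates are simple binomial proportions ``k/n``.  Confidence
intervals come in three flavours: Wilson score (default — good
small-sample behaviour, never leaves [0, 1]), logit-scale Wald, and exact
Clopper-Pearson.  Cluster sampling is accommodated through a design
effect ``deff``: Wilson uses the effective sample size ``n/deff`` (the
standard survey-statistics device), the logit interval inflates its
standard error by ``sqrt(deff)``, and Clopper-Pearson — an exact binomial
construction with no variance parameter — ignores it with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

CI_METHODS = ("wilson", "logit", "clopper_pearson")


@dataclass(frozen=True)
class PrevalenceEstimate:
    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    conf_level: float
    method: str
    deff: float

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion


@dataclass(frozen=True)
class ProportionComparison:
    """Two-sided Pearson chi-square comparison of two proportions.

    ``statistic``/``p_value`` are ``None`` when a margin of the 2x2 table
    is zero (the test is undefined); ``odds_ratio`` is ``None`` when its
    denominator is zero.
    """

    statistic: Optional[float]
    p_value: Optional[float]
    odds_ratio: Optional[float]
    k1: int
    n1: int
    k2: int
    n2: int


def estimate_prevalence(k: int, n: int, method: str = "wilson",
                        conf_level: float = 0.95,
                        deff: float = 1.0) -> PrevalenceEstimate:
    """Binomial prevalence ``k/n`` with a design-effect-adjusted CI."""
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < conf_level < 1.0:
        raise ValueError("conf_level must be in (0, 1)")
    if deff < 1.0:
        raise ValueError("deff must be >= 1")
    if method not in CI_METHODS:
        raise ValueError(f"method must be one of {CI_METHODS}")
    p = k / n
    alpha = 1.0 - conf_level
    if method == "wilson":
        lo, hi = proportion_confint(k / deff, n / deff, alpha=alpha,
                                    method="wilson")
    elif method == "clopper_pearson":
        if deff != 1.0:
            warnings.warn("Clopper-Pearson is an exact binomial interval; "
                          "the design effect is ignored", stacklevel=2)
        lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    else:  # logit
        if k == 0 or k == n:
            raise ValueError("logit interval undefined at k=0 or k=n; "
                             "use wilson or clopper_pearson")
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        logit = math.log(p / (1.0 - p))
        se = math.sqrt(deff) * math.sqrt(1.0 / k + 1.0 / (n - k))
        lo_l, hi_l = logit - z * se, logit + z * se
        lo = 1.0 / (1.0 + math.exp(-lo_l))
        hi = 1.0 / (1.0 + math.exp(-hi_l))
    # guard against float round-off at the boundaries: the interval must
    # stay inside [0, 1] and contain the point estimate
    lo = min(max(float(lo), 0.0), p)
    hi = max(min(float(hi), 1.0), p)
    return PrevalenceEstimate(numerator=k, denominator=n, proportion=p,
                              ci_low=lo, ci_high=hi,
                              conf_level=conf_level, method=method, deff=deff)


def subgroup_prevalence(records: pd.DataFrame, by: str,
                        label_column: str = "gold_standard_depressed",
                        method: str = "wilson", conf_level: float = 0.95,
                        deff: float = 1.0) -> pd.DataFrame:
    """Prevalence per level of a categorical cohort variable.

    Returns a DataFrame with one row per level (in order of first
    appearance sorted by label) and columns level, k, n, proportion,
    ci_low, ci_high.
    """
    if by not in records.columns:
        raise KeyError(f"unknown partition variable '{by}'")
    if label_column not in records.columns:
        raise KeyError(f"cohort lacks '{label_column}'")
    labels = records[label_column].astype(bool)
    rows = []
    for level, group in records.groupby(by, sort=True, observed=True):
        k = int(labels.loc[group.index].sum())
        n = len(group)
        est = estimate_prevalence(k, n, method=method, conf_level=conf_level,
                                  deff=deff)
        rows.append(dict(level=level, k=k, n=n, proportion=est.proportion,
                         ci_low=est.ci_low, ci_high=est.ci_high))
    return pd.DataFrame.from_records(rows)


def compare_proportions(k1: int, n1: int, k2: int, n2: int
                        ) -> ProportionComparison:
    """Pearson chi-square test (no continuity correction) of two
    proportions, plus the 2x2 odds ratio."""
    for k, n in ((k1, n1), (k2, n2)):
        if not 0 <= k <= n or n < 1:
            raise ValueError(f"invalid 2x2 margin: k={k}, n={n}")
    a, b = k1, n1 - k1
    c, d = k2, n2 - k2
    table = [[a, b], [c, d]]
    # zero row/column margin -> test undefined
    if (a + c == 0) or (b + d == 0):
        stat = p = None
    else:
        res = stats.chi2_contingency(table, correction=False)
        stat, p = float(res.statistic), float(res.pvalue)
    odds = (a * d) / (b * c) if b * c > 0 else None
    return ProportionComparison(statistic=stat, p_value=p, odds_ratio=odds,
                                k1=k1, n1=n1, k2=k2, n2=n2)
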