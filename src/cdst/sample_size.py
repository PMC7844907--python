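"""Sample-size planning for diagnostic-accuracy studies (Buderer's
formula) and the standard survey adjustments.

Buderer's formula sizes a study that must estimate a sensitivity (or
specificity) ``A`` to within an absolute half-width ``d`` at a given
confidence level, in a population where the relevant class (diseased for
sensitivity, non-diseased for specificity) has prevalence ``p``:

    n = z^2 * A * (1 - A) / (d^2 * p)

rounded up.  Dividing by ``p`` inflates the total sample so that the
*relevant subgroup* is large enough.  Design effect, finite-population
correction and non-response inflation are composable post-hoc adjustments,
kept separate from the base formula.
"""

from __future__ import annotations

import math
from typing import Optional

from scipy import stats


def buderer_n(expected_accuracy: float, d: float, p: float = 1.0,
              conf_level: float = 0.95) -> int:
    """Minimum total sample size to estimate a diagnostic accuracy.

    Parameters
    ----------
    expected_accuracy
        Anticipated sensitivity or specificity ``A``, strictly in (0, 1).
    d
        Absolute precision (CI half-width), in (0, 1).
    p
        Prevalence of the class the accuracy refers to — the disease
        prevalence for a sensitivity-driven design, ``1 - prevalence`` for
        a specificity-driven one.  ``p = 1`` sizes the subgroup itself.
    conf_level
        Two-sided confidence level; the z quantile is the exact normal
        quantile (1.959964... at 0.95), not the textbook 1.96.
    """
    if not 0.0 < expected_accuracy < 1.0:
        raise ValueError("expected_accuracy must be strictly between 0 and 1")
    if not 0.0 < d < 1.0:
        raise ValueError("absolute precision d must be in (0, 1)")
    if not 0.0 < p <= 1.0:
        raise ValueError("class prevalence p must be in (0, 1]")
    if not 0.0 < conf_level < 1.0:
        raise ValueError("conf_level must be in (0, 1)")
    z = stats.norm.ppf(1.0 - (1.0 - conf_level) / 2.0)
    n = z ** 2 * expected_accuracy * (1.0 - expected_accuracy) / (d ** 2 * p)
    return math.ceil(n)


def adjust_n(base_n: int, deff: float = 1.0, nonresponse_rate: float = 0.0,
             population_size: Optional[int] = None) -> int:
    """Survey adjustments applied in order: design effect, finite-population
    correction, non-response inflation; ceiling once at the end.

    ``population_size=None`` means an effectively unbounded population (no
    FPC).
    """
    if base_n < 1:
        raise ValueError("base_n must be >= 1")
    if deff < 1.0:
        raise ValueError("deff must be >= 1")
    if not 0.0 <= nonresponse_rate < 1.0:
        raise ValueError("nonresponse_rate must be in [0, 1)")
    n = float(base_n) * deff
    if population_size is not None:
        if population_size < 1:
            raise ValueError("population_size must be >= 1")
        n = n / (1.0 + (n - 1.0) / population_size)
    n = n / (1.0 - nonresponse_rate)
    return math.ceil(n)
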