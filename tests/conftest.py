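from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cdst.cohort import generate_cohort, study_spec

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_cohort() -> pd.DataFrame:
    """A cohort realising the reconstructed study skeleton (fixed seed)."""
    return generate_cohort(study_spec(seed=7))


def cohort_frame(scores, labels) -> pd.DataFrame:
    """Minimal cohort DataFrame from raw totals and gold-standard labels."""
    return pd.DataFrame({
        "total_score": np.asarray(scores, dtype=int),
        "gold_standard_depressed": np.asarray(labels, dtype=bool),
    })


def pair_count_auc(pos_scores, neg_scores) -> Fraction:
    """Brute-force Mann-Whitney AUC: P(S+ > S-) + 0.5 P(S+ = S-), exact."""
    wins = ties = 0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return Fraction(2 * wins + ties, 2 * len(pos_scores) * len(neg_scores))
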