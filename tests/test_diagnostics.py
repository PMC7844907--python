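import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from cdst.diagnostics import (CohortError, ConfusionMatrix,
                             accuracy_stats, confusion_at_cutoff,
                             exceedance_counts, operating_table,
                             optimal_cutoff, roc_curve)
from cdst.reconstruction import round_half_up

from conftest import cohort_frame, pair_count_auc


def random_cohort(rnd, max_n=120):
    """Random scored cohort with at least one positive and one negative."""
    n = rnd.randint(2, max_n)
    scores = [rnd.randint(0, 33) for _ in range(n)]
    labels = [rnd.random() < 0.3 for _ in range(n)]
    labels[0], labels[1] = True, False
    return cohort_frame(scores, labels)


def test_perfect_separation_has_no_errors():
    df = cohort_frame([33] * 5 + [0] * 20, [True] * 5 + [False] * 20)
    cm = confusion_at_cutoff(df, 6)
    assert (cm.fp, cm.fn) == (0, 0)
    assert (cm.tp, cm.tn) == (5, 20)


def test_confusion_counts_partition_the_cohort():
    df = random_cohort(random.Random(0))
    cm = confusion_at_cutoff(df, 6)
    assert cm.n == len(df)
    assert cm.n_pos == df["gold_standard_depressed"].sum()


def test_empty_cohort_is_an_error():
    with pytest.raises(CohortError, match="empty"):
        confusion_at_cutoff(cohort_frame([], []), 6)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ConfusionMatrix(tp=-1, fp=0, fn=0, tn=0)


def test_published_row_six_statistics():
    # counts recovered from the printed cutoff-6 row by rounding inversion
    s = accuracy_stats(ConfusionMatrix(tp=37, fp=9, fn=5, tn=245))
    assert round_half_up(100 * s.sensitivity, 1) == 88.1
    assert round_half_up(100 * s.specificity, 1) == 96.5
    assert round_half_up(100 * s.ppv, 1) == 80.4
    assert round_half_up(100 * s.npv, 1) == 98.0
    assert round_half_up(s.balanced_accuracy, 3) == 0.923


def test_published_row_seven_predictive_values():
    s = accuracy_stats(ConfusionMatrix(tp=33, fp=5, fn=9, tn=249))
    assert round_half_up(100 * s.ppv, 1) == 86.8
    assert round_half_up(100 * s.npv, 1) == 96.5


def test_zero_denominators_yield_undefined_markers():
    s = accuracy_stats(ConfusionMatrix(tp=0, fp=0, fn=5, tn=10))
    assert s.sensitivity == 0
    assert s.ppv is None
    assert s.balanced_accuracy is not None  # Se and Sp both defined
    s = accuracy_stats(ConfusionMatrix(tp=0, fp=0, fn=0, tn=10))
    assert s.sensitivity is None and s.balanced_accuracy is None


def test_operating_table_consistency_and_monotonicity(study_cohort):
    table = operating_table(study_cohort, 4, 10)
    assert len(table) == 7
    single = operating_table(study_cohort, 6, 6)
    assert single.rows[0][1] == table.stats_at(6)
    se = [s.sensitivity for _, s in table]
    sp = [s.specificity for _, s in table]
    assert all(a >= b for a, b in zip(se, se[1:]))
    assert all(a <= b for a, b in zip(sp, sp[1:]))


def test_operating_table_rejects_inverted_range(study_cohort):
    with pytest.raises(ValueError):
        operating_table(study_cohort, 10, 4)


def test_roc_endpoints_and_degenerate_aucs():
    df = cohort_frame([33] * 4 + [0] * 6, [True] * 4 + [False] * 6)
    roc = roc_curve(df)
    assert roc.auc == pytest.approx(1.0)
    assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
    assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
    assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)
    same = cohort_frame([5, 5, 7, 7], [True, False, True, False])
    assert roc_curve(same).auc == pytest.approx(0.5)


def test_roc_requires_both_classes():
    with pytest.raises(CohortError):
        roc_curve(cohort_frame([1, 2], [True, True]))


@given(st.randoms(use_true_random=False))
def test_roc_auc_equals_pair_counting_oracle(rnd):
    df = random_cohort(rnd)
    labels = df["gold_standard_depressed"].to_numpy()
    scores = df["total_score"].to_numpy()
    oracle = pair_count_auc(scores[labels].tolist(), scores[~labels].tolist())
    assert roc_curve(df).auc == pytest.approx(float(oracle), abs=1e-12)
    # independent library cross-check
    assert roc_curve(df).auc == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12)


@given(st.randoms(use_true_random=False))
def test_sweep_rates_non_increasing_in_cutoff(rnd):
    df = random_cohort(rnd)
    table = operating_table(df, 0, 33)
    se = [s.sensitivity for _, s in table]
    fpr = [1 - s.specificity for _, s in table]
    assert all(a >= b - 1e-12 for a, b in zip(se, se[1:]))
    assert all(a >= b - 1e-12 for a, b in zip(fpr, fpr[1:]))


def test_optimal_cutoff_prefers_larger_on_ties():
    # two cutoffs with identical balanced accuracy: tie goes high
    df = cohort_frame([0, 0, 5, 9, 9], [False, False, True, True, True])
    table = operating_table(df, 6, 9)
    ba = {c: s.balanced_accuracy for c, s in table}
    assert ba[7] == ba[8] == ba[9]
    assert optimal_cutoff(table) == 9


def test_optimal_cutoff_single_row(study_cohort):
    assert optimal_cutoff(operating_table(study_cohort, 5, 5)) == 5


def test_exceedance_counts_match_confusion(study_cohort):
    tp, fp = exceedance_counts(study_cohort, 4, 10)
    for i, cutoff in enumerate(range(4, 11)):
        cm = confusion_at_cutoff(study_cohort, cutoff)
        assert (tp[i], fp[i]) == (cm.tp, cm.fp)
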