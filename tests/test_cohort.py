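import io as stdio

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdst.cohort import (CohortSpec, CohortSpecError, decompose_score,
                         generate_cohort, study_spec)
from cdst.diagnostics import exceedance_counts, operating_table
from cdst.instrument import score_cdst
from cdst.io import with_age_band
from cdst.reconstruction import ScoreHistogram
from cdst.tables import CUTOFF_TABLE, demographic_margins


def small_histogram(group, counts):
    return ScoreHistogram(group=group, kmin=4, kmax=10, counts=counts)


def test_default_spec_realises_the_study_skeleton(study_cohort):
    assert len(study_cohort) == 296
    assert study_cohort["gold_standard_depressed"].sum() == 42


def test_score_histograms_match_exactly(study_cohort):
    spec = study_spec()
    tp, fp = exceedance_counts(study_cohort, 4, 10)
    assert tuple(tp) == (40, 39, 37, 33, 31, 24, 17)
    assert tuple(fp) == (34, 22, 9, 5, 2, 1, 1)
    assert spec.pos_histogram.total == 42


def test_demographic_margins_match_exactly(study_cohort):
    margins = demographic_margins()
    frame = with_age_band(study_cohort)
    for var, levels in margins.items():
        if var == "viral_suppressed":
            observed = frame["viral_suppressed"].map(
                {True: "yes", False: "no"}).value_counts().to_dict()
        else:
            observed = frame[var].value_counts().to_dict()
        assert observed == {k: v for k, v in levels.items() if v}, var


def test_depression_cross_classification_matches(study_cohort):
    frame = with_age_band(study_cohort)
    pos = frame[frame["gold_standard_depressed"]]
    assert pos["province"].value_counts().to_dict() == {
        "West": 17, "Kigali": 9, "East": 7, "South": 7, "North": 2}
    assert pos["age_band"].value_counts().to_dict() == {
        "13-14": 28, "10-12": 11, "7-9": 3}
    assert pos["sex"].value_counts().to_dict() == {"female": 26, "male": 16}


def test_same_seed_is_byte_identical():
    from cdst.io import write_cohort

    def render(seed):
        frame = generate_cohort(study_spec(seed=seed))
        buf = stdio.StringIO()
        out = frame.copy()
        for col in ("viral_suppressed", "gold_standard_depressed"):
            out[col] = out[col].astype(int)
        out.to_csv(buf, index=False, lineterminator="\n")
        return buf.getvalue()

    assert render(11) == render(11)
    assert render(11) != render(12)


def test_cutoff_range_statistics_invariant_to_seed_and_bin_rules():
    frames = [
        generate_cohort(study_spec(seed=1)),
        generate_cohort(study_spec(seed=99)),
        generate_cohort(study_spec(seed=1, high_bin_rule="uniform")),
    ]
    tables = [operating_table(f, 4, 10).to_dataframe() for f in frames]
    for other in tables[1:]:
        pd.testing.assert_frame_equal(tables[0], other)


def test_generated_cohort_reproduces_every_printed_cell(study_cohort):
    from cdst.reconstruction import round_half_up

    table = operating_table(study_cohort, 4, 10)
    for row in CUTOFF_TABLE:
        s = table.stats_at(row.cutoff)
        assert round_half_up(100 * s.sensitivity, 1) == row.sensitivity_pct
        assert round_half_up(100 * s.specificity, 1) == row.specificity_pct
        assert round_half_up(100 * s.ppv, 1) == row.ppv_pct
        assert round_half_up(100 * s.npv, 1) == row.npv_pct
        assert round_half_up(s.balanced_accuracy, 3) == row.auc


def test_all_negative_spec_generates_single_class():
    spec = CohortSpec(
        n_pos=0, n_neg=10,
        pos_histogram=small_histogram("positive", dict.fromkeys(
            ScoreHistogram.bin_labels(4, 10), 0)),
        neg_histogram=small_histogram("negative", {
            "<4": 6, "4": 1, "5": 1, "6": 1, "7": 1, "8": 0, "9": 0,
            ">=10": 0}),
        margins={"sex": {"male": 5, "female": 5}},
        seed=3,
    )
    frame = generate_cohort(spec)
    assert not frame["gold_standard_depressed"].any()
    from cdst.diagnostics import CohortError, roc_curve
    with pytest.raises(CohortError):
        roc_curve(frame)


def test_infeasible_joint_margin_is_named():
    margins = {"sex": {"male": 5, "female": 5}}
    with pytest.raises(CohortSpecError, match="sex"):
        CohortSpec(
            n_pos=4, n_neg=6,
            pos_histogram=small_histogram("positive", {
                "<4": 0, "4": 4, "5": 0, "6": 0, "7": 0, "8": 0, "9": 0,
                ">=10": 0}),
            neg_histogram=small_histogram("negative", {
                "<4": 6, "4": 0, "5": 0, "6": 0, "7": 0, "8": 0, "9": 0,
                ">=10": 0}),
            margins=margins,
            joint_positive={"sex": {"male": 6, "female": -2}},
        )


def test_histogram_total_mismatch_rejected():
    with pytest.raises(CohortSpecError, match="histogram"):
        study_spec(n_pos=41)


@pytest.mark.parametrize("total", [0, 33])
def test_extreme_scores_force_the_decomposition(total):
    rng = np.random.default_rng(0)
    values = decompose_score(total, rng)
    assert values == tuple([total // 11] * 11)


@given(st.integers(0, 33))
def test_decomposition_roundtrips_through_scoring(total):
    rng = np.random.default_rng(total)
    values = decompose_score(total, rng)
    assert all(0 <= v <= 3 for v in values)
    assert score_cdst(list(values)) == total


def test_decomposition_is_uniform_over_compositions():
    # by symmetry the uniform-composition expectation of each item is s/11
    rng = np.random.default_rng(42)
    draws = np.array([decompose_score(6, rng) for _ in range(4000)])
    assert draws.mean(axis=0) == pytest.approx([6 / 11] * 11, abs=0.06)


def test_age_years_consistent_with_bands(study_cohort):
    frame = with_age_band(study_cohort)
    ages = frame["age_years"]
    assert ages.between(7, 14).all()
    assert (frame.loc[frame["age_band"] == "7-9", "age_years"] <= 9).all()
    assert (frame.loc[frame["age_band"] == "13-14", "age_years"] >= 13).all()


def test_calibrated_age_mode_targets_published_mean():
    frame = generate_cohort(study_spec(seed=5, age_mode="calibrated"))
    assert frame["age_years"].mean() == pytest.approx(12.0, abs=0.35)


def test_facility_assignment_respects_province_and_residence():
    frame = generate_cohort(study_spec(seed=2, with_facilities=True))
    assert all(fid.startswith(f"{prov}-") for fid, prov in
               zip(frame["facility_id"], frame["province"]))
    urban = frame["residence"] == "urban"
    assert frame.loc[urban, "facility_id"].str.contains("-U").all()
    assert frame.loc[~urban, "facility_id"].str.contains("-R").all()
    # 2 urban + 3 rural sites per province at most
    per_province = frame.groupby("province")["facility_id"].nunique()
    assert (per_province <= 5).all()
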