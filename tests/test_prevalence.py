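import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdst.io import with_age_band
from cdst.prevalence import (compare_proportions, estimate_prevalence,
                             subgroup_prevalence)
from cdst.reconstruction import round_half_up


def test_overall_point_estimate_displays_study_prevalence():
    est = estimate_prevalence(42, 296)
    assert est.proportion == pytest.approx(42 / 296)
    assert round_half_up(est.percent, 1) == 14.2


def test_wilson_interval_matches_closed_form():
    # Wilson closed form evaluated independently: [0.1067, 0.1862]
    est = estimate_prevalence(42, 296, method="wilson", conf_level=0.95)
    assert est.ci_low == pytest.approx(0.10672, abs=5e-5)
    assert est.ci_high == pytest.approx(0.18624, abs=5e-5)
    assert est.ci_low <= est.proportion <= est.ci_high


def test_zero_numerator_boundary():
    est = estimate_prevalence(0, 50, method="wilson")
    assert est.proportion == 0.0
    assert est.ci_low == 0.0
    assert est.ci_high > 0.0


@pytest.mark.parametrize("method", ["wilson", "logit"])
def test_design_effect_strictly_widens_interval(method):
    plain = estimate_prevalence(42, 296, method=method, deff=1.0)
    inflated = estimate_prevalence(42, 296, method=method, deff=1.2)
    assert inflated.ci_low < plain.ci_low
    assert inflated.ci_high > plain.ci_high


def test_clopper_pearson_warns_and_ignores_deff():
    with pytest.warns(UserWarning, match="design effect"):
        est = estimate_prevalence(42, 296, method="clopper_pearson", deff=1.2)
    plain = estimate_prevalence(42, 296, method="clopper_pearson")
    assert (est.ci_low, est.ci_high) == (plain.ci_low, plain.ci_high)


@given(st.integers(1, 12))
def test_interval_narrows_with_sample_size_at_fixed_rate(mult):
    small = estimate_prevalence(5, 40)
    large = estimate_prevalence(5 * mult, 40 * mult)
    assert (large.ci_high - large.ci_low) <= (small.ci_high - small.ci_low)


@given(st.integers(0, 60), st.sampled_from(["wilson", "clopper_pearson"]))
def test_every_interval_contains_the_point_estimate(k, method):
    est = estimate_prevalence(k, 60, method=method)
    assert est.ci_low <= est.proportion <= est.ci_high


@pytest.mark.parametrize("bad", [dict(k=-1, n=10), dict(k=11, n=10),
                                 dict(k=1, n=10, deff=0.5),
                                 dict(k=1, n=10, conf_level=1.0)])
def test_invalid_prevalence_inputs_rejected(bad):
    with pytest.raises(ValueError):
        estimate_prevalence(**bad)


def test_subgroup_prevalences_reproduce_published_points(study_cohort):
    by_province = subgroup_prevalence(study_cohort, "province")
    points = {r.level: round_half_up(100 * r.proportion, 1)
              for r in by_province.itertuples()}
    assert points == {"East": 11.7, "West": 24.3, "Kigali": 15.8,
                      "North": 3.8, "South": 12.5}
    by_sex = subgroup_prevalence(study_cohort, "sex")
    points = {r.level: round_half_up(100 * r.proportion, 1)
              for r in by_sex.itertuples()}
    assert points == {"male": 11.0, "female": 17.2}
    by_age = subgroup_prevalence(with_age_band(study_cohort), "age_band")
    points = {r.level: round_half_up(100 * r.proportion, 1)
              for r in by_age.itertuples()}
    assert points == {"7-9": 6.5, "10-12": 9.6, "13-14": 20.6}


def test_subgroup_margins_sum_to_overall(study_cohort):
    sub = subgroup_prevalence(study_cohort, "province")
    assert sub["k"].sum() == 42
    assert sub["n"].sum() == 296


def test_unknown_partition_variable_errors(study_cohort):
    with pytest.raises(KeyError):
        subgroup_prevalence(study_cohort, "hair_colour")


def test_adolescents_and_western_province_differ_significantly():
    # age 13-14 vs 7-12 and West vs rest, counts recovered from the tables
    adolescents = compare_proportions(28, 136, 14, 160)
    assert adolescents.p_value < 0.05
    west = compare_proportions(17, 70, 25, 226)
    assert west.p_value < 0.05


def test_identical_proportions_give_p_one():
    same = compare_proportions(5, 50, 5, 50)
    assert same.p_value == pytest.approx(1.0)
    assert same.statistic == pytest.approx(0.0)
    assert same.odds_ratio == pytest.approx(1.0)


def test_zero_margin_gives_undefined_statistic():
    degenerate = compare_proportions(0, 10, 0, 10)
    assert degenerate.statistic is None and degenerate.p_value is None
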