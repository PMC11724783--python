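"""Means with CIs, one-way ANOVA, compliance tables and report output."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nppm import (assess_products, compliance_table, mean_ci, nutrient_anova,
                  one_way_anova, report, verdict_frame)
from nppm.summary_stats import round_half_up


@pytest.mark.parametrize("x,expected", [
    (0.4, 0), (0.5, 1), (1.5, 2), (2.49, 2), (66.5, 67), (45.25, 45),
])
def test_round_half_up(x, expected):
    assert round_half_up(x) == expected


def test_mean_ci_two_points_frozen_value():
    # closed form: mean 2, sd sqrt(2), SE 1, t(0.975, df=1) = 12.7062...
    mean, lo, hi = mean_ci([1.0, 3.0])
    assert mean == 2.0
    assert lo == pytest.approx(2.0 - 12.706204736432095, abs=1e-9)
    assert hi == pytest.approx(2.0 + 12.706204736432095, abs=1e-9)


def test_mean_ci_degenerate_inputs():
    mean, lo, hi = mean_ci([5.0, 5.0, 5.0])
    assert (mean, lo, hi) == (5.0, 5.0, 5.0)  # zero variance
    mean, lo, hi = mean_ci([7.0])
    assert mean == 7.0 and math.isnan(lo) and math.isnan(hi)
    with pytest.raises(ValueError):
        mean_ci([])


def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(3)
    g1, g2 = rng.normal(0, 1, 12), rng.normal(0.4, 1, 17)
    res = one_way_anova([g1, g2])
    t, _ = stats.ttest_ind(g1, g2, equal_var=True)
    assert res.f_statistic == pytest.approx(t ** 2, abs=1e-10)
    assert res.df_between == 1 and res.df_within == 27


def test_anova_degrees_of_freedom_and_exclusion():
    groups = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [9.0]]
    res = one_way_anova(groups, min_group_n=2)  # singleton excluded
    assert res.df_between == 1 and res.df_within == 4
    res = one_way_anova(groups, min_group_n=1)
    assert res.df_between == 2 and res.df_within == 4


def test_anova_degenerate_zero_within_variance():
    res = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
    assert res.degenerate and res.p_value == 0.0
    assert math.isinf(res.f_statistic)


def test_anova_requires_two_groups():
    with pytest.raises(ValueError):
        one_way_anova([[1.0, 2.0]])


def test_nutrient_anova_separates_categories(small_survey):
    records, _ = small_survey
    results = nutrient_anova(records)
    # energy density differs hugely between purees (~65 kcal) and
    # snacks (~420 kcal): the ANOVA must detect it decisively
    assert results["energy_kcal"].p_value < 0.001
    assert all(r.p_value < 0.001 for r in results.values())
    k = results["energy_kcal"].df_between + 1
    n = results["energy_kcal"].df_within + k
    assert n == sum(1 for r in records if r.category.value in
                    ("Cereals", "Dairy", "FruitVeg", "Meals", "Snacks"))


def test_compliance_table_arithmetic(small_survey):
    records, _ = small_survey
    assessments = assess_products(records)
    table = compliance_table(assessments, by="criterion")
    vf = verdict_frame(assessments)
    row = table[table.criterion == "overall_nutrient"].iloc[0]
    n_fail = int((~vf.nutrient_compliant.astype(bool)).sum())
    assert row.n_fail == n_fail
    assert row.pct_fail == round_half_up(100 * n_fail / row.n_applicable)
    # every row internally consistent
    for _, r in table.iterrows():
        assert 0 <= r.pct_fail <= 100
        assert r.n_fail <= r.n_applicable <= r.n
        assert r.pct_fail == round_half_up(100 * r.n_fail / r.n_applicable)


def test_compliance_table_quarter_failure():
    from nppm import generate_products, default_config
    config = default_config()
    config.n = 4
    config.category_mix = {"Meals": 1.0}
    config.overall_fail = {"Meals": 0.25}
    config.criterion_fail = {"Meals": {"salt": 0.25}}
    config.added_sugar_fail = {"Meals": 0.0}
    records, _ = generate_products(config, seed=5)
    table = compliance_table(assess_products(records), by="criterion")
    overall = table[table.criterion == "overall_nutrient"].iloc[0]
    assert overall.n_applicable == 4 and overall.n_fail == 1
    assert overall.pct_fail == 25


def test_compliance_table_permutation_invariant(small_survey):
    records, _ = small_survey
    assessments = assess_products(records)
    a = compliance_table(assessments, by="category")
    rng = np.random.default_rng(0)
    shuffled = [assessments[i] for i in rng.permutation(len(assessments))]
    b = compliance_table(shuffled, by="category")
    pd.testing.assert_frame_equal(
        a.sort_values(["stratum", "criterion"]).reset_index(drop=True),
        b.sort_values(["stratum", "criterion"]).reset_index(drop=True))


def test_report_writes_stable_tables(small_survey, tmp_path):
    records, _ = small_survey
    assessments = assess_products(records)
    first = report(records, assessments, tmp_path / "a")
    second = report(records, assessments, tmp_path / "b")
    assert set(first) == set(second)
    for name in first:
        assert first[name].read_bytes() == second[name].read_bytes()
    counts = pd.read_csv(first["counts"])
    assert counts[counts.dimension == "category"].n.sum() == len(records)


def test_report_empty_assessments(tmp_path):
    paths = report([], [], tmp_path)
    for p in paths.values():
        assert p.exists()
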