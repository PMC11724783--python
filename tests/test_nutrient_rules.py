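"""Nutrient-composition criteria: thresholds, bases, overall verdict."""

import pytest
from hypothesis import given, strategies as st

from nppm import (Category, ProductRecord, RuleTable, assess_nutrients,
                  energy_rule, fat_rule, marketability_rule, per_100kcal,
                  protein_rule, salt_rule, sugar_pct_rule)


def product(category="Meals", flags=(), **kw):
    defaults = dict(product_id="t", category=Category(category),
                    subcategory_flags=frozenset(flags))
    defaults.update(kw)
    return ProductRecord(**defaults)


def meal(**kw):
    return product("Meals", flags=("is_savoury_meal",), **kw)


# ---------------------------------------------------------------------------
# per-100 kcal basis
# ---------------------------------------------------------------------------

def test_per_100kcal_arithmetic():
    assert per_100kcal(3.1, 69) == pytest.approx(4.4928, abs=1e-3)
    assert per_100kcal(7.0, 100) == 7.0  # identity at 100 kcal/100 g
    assert per_100kcal(1.0, 0) is None
    assert per_100kcal(None, 69) is None


@given(st.floats(0.1, 50), st.floats(10, 500), st.floats(0.01, 100))
def test_per_100kcal_ratio_invariance(value, energy, k):
    base = per_100kcal(value, energy)
    scaled = per_100kcal(value * k, energy * k)
    assert scaled == pytest.approx(base, rel=1e-9)


# ---------------------------------------------------------------------------
# single criteria at their printed thresholds (inclusive boundaries)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("energy,expected", [(60.0, True), (59.9, False),
                                             (60.1, True)])
def test_energy_rule_meals_boundary(rules, energy, expected):
    result = energy_rule(meal(energy_kcal_100g=energy), rules)
    assert result.applicable and result.passed is expected


def test_energy_rule_snack_per_serving(rules):
    r = energy_rule(product("Snacks", energy_kcal_100g=400, serving_g=10),
                    rules)
    assert r.passed is True and r.observed == pytest.approx(40.0)
    r = energy_rule(product("Snacks", energy_kcal_100g=400, serving_g=13),
                    rules)
    assert r.passed is False  # 52 kcal per serving
    r = energy_rule(product("Snacks", energy_kcal_100g=400), rules)
    assert r.applicable and r.passed is None  # serving size missing


def test_energy_rule_dry_cereal_prepared(rules):
    cereal = product("Cereals", flags=("is_dry_cereal",),
                     energy_kcal_100g=390, prepared_energy_kcal_100g=80)
    assert energy_rule(cereal, rules).passed is True
    cereal = product("Cereals", flags=("is_dry_cereal",),
                     energy_kcal_100g=390, prepared_energy_kcal_100g=79.9)
    assert energy_rule(cereal, rules).passed is False


def test_energy_rule_dry_cereal_fallback_warns(rules):
    cereal = product("Cereals", flags=("is_dry_cereal",),
                     energy_kcal_100g=390)
    r = energy_rule(cereal, rules)
    assert r.passed is True and "dry label" in r.note


@pytest.mark.parametrize("value,expected", [(5.5, True), (5.6, False)])
def test_protein_rule_milk_cereal_maximum(rules, value, expected):
    cereal = product("Cereals", flags=("is_dry_cereal", "contains_milk"),
                     energy_kcal_100g=100, protein_g_100g=value)
    assert protein_rule(cereal, rules).passed is expected


@pytest.mark.parametrize("value,expected", [(3.0, True), (2.9, False)])
def test_protein_rule_savoury_meal_minimum(rules, value, expected):
    assert protein_rule(
        meal(energy_kcal_100g=100, protein_g_100g=value),
        rules).passed is expected


def test_protein_rule_meat_meal_elevated_minimum(rules):
    meat = product("Meals",
                   flags=("is_savoury_meal", "contains_meat_poultry_fish"),
                   energy_kcal_100g=100, protein_g_100g=3.5)
    r = protein_rule(meat, rules)
    assert r.threshold == 4.0 and r.passed is False


@pytest.mark.parametrize("value,expected", [(4.5, True), (4.6, False)])
def test_fat_rule_default_maximum(rules, value, expected):
    assert fat_rule(meal(energy_kcal_100g=100, fat_g_100g=value),
                    rules).passed is expected


def test_fat_rule_meat_meal_allowance(rules):
    meat = product("Meals",
                   flags=("is_savoury_meal", "contains_meat_poultry_fish"),
                   energy_kcal_100g=100, fat_g_100g=6.0)
    assert fat_rule(meat, rules).passed is True


@pytest.mark.parametrize("value,cheese,expected", [
    (0.125, False, True), (0.126, False, False), (0.25, True, True),
    (0.26, True, False),
])
def test_salt_rule_with_cheese_allowance(rules, value, cheese, expected):
    flags = ("is_savoury_meal", "contains_cheese") if cheese \
        else ("is_savoury_meal",)
    p = product("Meals", flags=flags, energy_kcal_100g=100,
                salt_g_100g=value)
    assert salt_rule(p, rules).passed is expected


def test_sugar_pct_rule_boundary_and_scope(rules):
    assert sugar_pct_rule(meal(), 15.0, rules).passed is True
    assert sugar_pct_rule(meal(), 15.1, rules).passed is False
    # meal at Table-2-like means: 2.5 g sugar, 69 kcal -> 14.5 %E
    r = sugar_pct_rule(meal(energy_kcal_100g=69, total_sugar_g_100g=2.5),
                       rules=rules)
    assert r.passed is True and r.observed == pytest.approx(14.49, abs=0.01)
    fruity = product("Snacks", flags=("is_fruit_based_snack",))
    assert sugar_pct_rule(fruity, 90.0, rules).applicable is False


@pytest.mark.parametrize("category,marketable", [
    ("Confectionery", False), ("Drinks", False), ("Meals", True),
    ("FruitVeg", True),
])
def test_marketability(rules, category, marketable):
    assert marketability_rule(product(category), rules).passed is marketable


# ---------------------------------------------------------------------------
# overall verdict
# ---------------------------------------------------------------------------

def compliant_meal(**kw):
    fields = dict(energy_kcal_100g=100.0, protein_g_100g=4.0,
                  fat_g_100g=2.0, total_sugar_g_100g=2.0, salt_g_100g=0.1,
                  ingredients=[("chicken", None), ("carrots", None)])
    fields.update(kw)
    return meal(**fields)


def test_assess_all_pass_is_compliant(rules):
    a = assess_nutrients(compliant_meal(), rules)
    assert a.nutrient_compliant is True and a.marketable


def test_assess_single_failure_fails_overall(rules):
    a = assess_nutrients(compliant_meal(salt_g_100g=0.2), rules)
    assert a.nutrient_compliant is False
    fails = [r.criterion for r in a.nutrient_results if r.counts_as_fail]
    assert fails == ["salt"]


def test_assess_confectionery_never_compliant(rules):
    sweet = product("Confectionery", energy_kcal_100g=100,
                    protein_g_100g=4, fat_g_100g=2, total_sugar_g_100g=2,
                    salt_g_100g=0.1)
    a = assess_nutrients(sweet, rules)
    assert a.nutrient_compliant is False and not a.marketable
    # nutrient panel not evaluated for non-marketable categories
    assert all(not r.applicable for r in a.nutrient_results
               if r.criterion != "marketability")


def test_vacuous_criterion_never_changes_verdict(rules):
    # sugar_pct does not apply to fruit-based snacks: any sugar level
    # leaves the overall verdict unchanged.
    base = dict(product_id="t", category=Category("Snacks"),
                subcategory_flags=frozenset({"is_fruit_based_snack"}),
                energy_kcal_100g=400.0, serving_g=10.0, protein_g_100g=4.0,
                fat_g_100g=10.0, salt_g_100g=0.15,
                ingredients=[("apple", None)])
    verdicts = {
        assess_nutrients(ProductRecord(**base, total_sugar_g_100g=s),
                         rules).nutrient_compliant
        for s in (0.0, 30.0, 90.0)
    }
    assert len(verdicts) == 1


def test_incomplete_panel_policies(rules):
    incomplete = compliant_meal(salt_g_100g=None)
    a = assess_nutrients(incomplete, rules)
    assert a.nutrient_compliant is True       # default: assess what exists
    assert any("incomplete" in n for n in a.notes)
    strict = RuleTable(rules.entries, incomplete_policy="strict",
                       fop_thresholds=rules.fop_thresholds)
    assert assess_nutrients(incomplete, strict).nutrient_compliant is False


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

@given(st.floats(0.0, 40.0), st.floats(0.1, 40.0))
def test_sugar_monotone_more_sugar_never_rescues(sugar, extra):
    rules = RuleTable.default()
    lo = sugar_pct_rule(meal(energy_kcal_100g=100, total_sugar_g_100g=sugar),
                        rules=rules)
    hi = sugar_pct_rule(
        meal(energy_kcal_100g=100, total_sugar_g_100g=min(sugar + extra, 100)),
        rules=rules)
    if lo.passed is False:
        assert hi.passed is False


@given(st.floats(0.0, 1.0), st.floats(0.001, 1.0))
def test_salt_monotone_less_salt_never_breaks(salt, less):
    rules = RuleTable.default()
    hi = salt_rule(meal(energy_kcal_100g=100, salt_g_100g=salt), rules)
    lo = salt_rule(meal(energy_kcal_100g=100,
                        salt_g_100g=max(salt - less, 0.0)), rules)
    if hi.passed is True:
        assert lo.passed is True


def test_rule_table_yaml_roundtrip(rules, tmp_path):
    path = tmp_path / "rules.yaml"
    rules.to_yaml(path)
    back = RuleTable.from_yaml(path)
    assert back.to_dict() == rules.to_dict()
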