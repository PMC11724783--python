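"""Promotional requirements: claims, age labels, breastfeeding, spouts,
name clarity, ingredient lists, preparation instructions, FOP label."""

import pytest
from hypothesis import given, strategies as st

from nppm import (Category, ClaimLexicon, LabelInfo, ProductRecord,
                  age_label_rule, assess_promotion,
                  breastfeeding_statement_rule, claims_rule, fop_label_rule,
                  ingredient_list_rule, name_clarity_rule,
                  preparation_instructions_rule, spout_warning_rule)


def label(**kw):
    return LabelInfo(**kw)


def product(category="Meals", **kw):
    defaults = dict(product_id="t", category=Category(category))
    defaults.update(kw)
    return ProductRecord(**defaults)


@pytest.fixture(scope="module")
def claims():
    return ClaimLexicon.default()


@pytest.mark.parametrize("texts,passes", [
    (["no added sugar"], False),           # nutrition claim
    (["supports healthy growth"], False),  # health claim
    (["organic"], False),                  # marketing claim
    (["contains milk"], True),             # allergen statement, not a claim
    ([], True),
])
def test_claims_rule(claims, texts, passes):
    assert claims_rule(label(claim_texts=texts), claims).passed is passes


@pytest.mark.parametrize("months,passes", [(4, False), (5, False),
                                           (6, True), (12, True),
                                           (None, False)])
def test_age_label_rule_six_month_floor(months, passes):
    assert age_label_rule(months).passed is passes


@pytest.mark.parametrize("has,adequate,passes", [
    (True, True, True), (True, False, False), (False, False, False),
])
def test_breastfeeding_statement_rule(has, adequate, passes):
    lab = label(has_breastfeeding_statement=has,
                breastfeeding_statement_adequate=adequate)
    assert breastfeeding_statement_rule(lab).passed is passes


def test_spout_warning_rule():
    pouch = product(label=label(has_spout=True, has_spout_warning=False))
    assert spout_warning_rule(pouch).passed is False
    warned = product(label=label(has_spout=True, has_spout_warning=True))
    assert spout_warning_rule(warned).passed is True
    jar = product(label=label(has_spout=False))
    assert spout_warning_rule(jar).applicable is False


def test_name_clarity_heuristic():
    ok = product(name="Apple & Banana Porridge",
                 ingredients=[("oats", None), ("apple", None),
                              ("banana", None)])
    assert name_clarity_rule(ok).passed is True
    bad = product(name="Strawberry Treat",
                  ingredients=[("apple purée", None), ("sugar", None)])
    assert name_clarity_rule(bad).passed is False
    # food token present but only beyond the top-3 ingredients
    deep = product(name="Mango Bites",
                   ingredients=[("oats", None), ("apple", None),
                                ("banana", None), ("mango", None)])
    assert name_clarity_rule(deep).passed is False
    assert name_clarity_rule(deep, top_k=4).passed is True


def test_name_clarity_manual_override_wins():
    p = product(name="Strawberry Treat",
                ingredients=[("apple purée", None)],
                label=label(name_reflects_main_ingredients=True))
    assert name_clarity_rule(p).passed is True
    assert "manual" in name_clarity_rule(p).note


def test_name_clarity_empty_ingredients_not_assessable():
    p = product(name="Apple Pouch", ingredients=[])
    r = name_clarity_rule(p)
    assert r.applicable and r.passed is None


def test_ingredient_list_rule():
    assert ingredient_list_rule(
        label(ingredient_proportions_declared=True)).passed is True
    assert ingredient_list_rule(
        label(ingredient_proportions_declared=False)).passed is False


def test_preparation_instructions_applicability():
    lab = label(has_preparation_instructions=False)
    assert preparation_instructions_rule(lab, "Cereals").passed is False
    assert preparation_instructions_rule(
        label(has_preparation_instructions=True), "Cereals").passed is True
    # ready-to-eat categories are out of scope by default config
    assert preparation_instructions_rule(lab, "Snacks").applicable is False
    # ...but applicability is config-driven
    assert preparation_instructions_rule(
        lab, "Snacks", required_categories=("Snacks",)).passed is False


def test_fop_label_rule():
    assert fop_label_rule(label(has_fop_sugar_flag=True), True).passed is True
    assert fop_label_rule(label(has_fop_sugar_flag=False), True).passed is False
    assert fop_label_rule(label(has_fop_sugar_flag=False),
                          False).applicable is False


def _clean_product(**kw):
    fields = dict(
        product_id="t", category=Category("Meals"),
        lower_age_months=6,
        name="Chicken Meal",
        ingredients=[("chicken", None), ("carrots", None)],
        label=label(
            claim_texts=[],
            has_breastfeeding_statement=True,
            breastfeeding_statement_adequate=True,
            has_preparation_instructions=True,
            ingredient_proportions_declared=True,
        ),
    )
    fields.update(kw)
    return ProductRecord(**fields)


def test_assess_promotion_all_pass(claims):
    results, compliant = assess_promotion(_clean_product(), claims)
    assert compliant is True
    assert all(r.passed is not False for r in results if r.applicable)


def test_assess_promotion_single_claim_fails_overall(claims):
    p = _clean_product()
    p.label.claim_texts = ["no added sugar"]
    results, compliant = assess_promotion(p, claims)
    assert compliant is False
    failing = [r.criterion for r in results if r.counts_as_fail]
    assert failing == ["claims"]


def test_assess_promotion_matches_rule_by_rule_conjunction(claims,
                                                           small_survey):
    """The combined verdict equals the conjunction of individually
    evaluated applicable rules (order independence)."""
    records, _ = small_survey
    for p in records[:50]:
        results, compliant = assess_promotion(p, claims)
        manual = all(
            r.passed for r in results if r.applicable and r.passed is not None)
        assert compliant is manual


@given(st.lists(st.sampled_from(
    ["no added sugar", "organic", "yummy", "source of iron"]),
    min_size=0, max_size=4))
def test_adding_claims_never_rescues(texts):
    claims = ClaimLexicon.default()
    base = claims_rule(label(claim_texts=texts), claims)
    more = claims_rule(label(claim_texts=texts + ["delicious"]), claims)
    assert more.passed is False or base.passed is True
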