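"""End-to-end assessment: nutrient rules + sugar profile + promotion.

`assess_products` turns validated records into full
:class:`~nppm.nutrient_rules.ProductAssessment` objects;
`verdict_frame` flattens them into one wide row per product
(``True``/``False`` per criterion, ``NA`` when not applicable or not
assessable), which is the shape used for aggregation and for checking
against a synthetic ground-truth ledger.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .ingestion import ProductRecord, bucket_age
from .nutrient_rules import (NUTRIENT_CRITERIA, ProductAssessment, RuleTable,
                             assess_nutrients)
from .promotion_rules import (DEFAULT_PREPARATION_CATEGORIES, PROMOTION_CRITERIA,
                              ClaimLexicon, assess_promotion)
from .sugar_profile import SugarLexicon, profile_product


def assess_product(
    p: ProductRecord,
    rules: Optional[RuleTable] = None,
    sugar_lexicon: Optional[SugarLexicon] = None,
    claim_lexicon: Optional[ClaimLexicon] = None,
    food_words: Optional[frozenset[str]] = None,
    preparation_categories: Sequence[str] = DEFAULT_PREPARATION_CATEGORIES,
) -> ProductAssessment:
    """Assess one product on every nutrient and promotion criterion."""
    rules = rules or RuleTable.default()
    sugar = profile_product(p, sugar_lexicon, rules)
    assessment = assess_nutrients(p, rules, sugar)
    results, compliant = assess_promotion(
        p, claim_lexicon, fop_required=sugar.fop_flag_required,
        food_words=food_words, preparation_categories=preparation_categories)
    assessment.promotion_results = results
    assessment.promotion_compliant = compliant
    return assessment


def assess_products(
    records: Sequence[ProductRecord],
    rules: Optional[RuleTable] = None,
    sugar_lexicon: Optional[SugarLexicon] = None,
    claim_lexicon: Optional[ClaimLexicon] = None,
    food_words: Optional[frozenset[str]] = None,
    preparation_categories: Sequence[str] = DEFAULT_PREPARATION_CATEGORIES,
) -> list[ProductAssessment]:
    """Assess a list of products (lexicons and rule table loaded once)."""
    rules = rules or RuleTable.default()
    sugar_lexicon = sugar_lexicon or SugarLexicon.default()
    claim_lexicon = claim_lexicon or ClaimLexicon.default()
    if food_words is None:
        from .promotion_rules import default_food_words
        food_words = default_food_words()
    return [
        assess_product(p, rules, sugar_lexicon, claim_lexicon, food_words,
                       preparation_categories)
        for p in records
    ]


ALL_CRITERIA = ("marketability",) + NUTRIENT_CRITERIA + PROMOTION_CRITERIA


def _tri(result) -> object:
    """True/False for assessed results, pd.NA for vacuous/unassessable."""
    if result is None or not result.applicable or result.passed is None:
        return pd.NA
    return bool(result.passed)


def verdict_frame(assessments: Sequence[ProductAssessment]) -> pd.DataFrame:
    """One wide row per product with per-criterion verdicts."""
    rows = []
    for a in assessments:
        bucket = bucket_age(a.lower_age_months)
        row = {
            "product_id": a.product_id,
            "category": a.category.value,
            "age_bucket": None if bucket is None else bucket.value,
            "marketable": a.marketable,
            "nutrient_compliant": a.nutrient_compliant,
            "promotion_compliant": a.promotion_compliant,
            "fop_required": a.fop_flag_required,
        }
        row["marketability"] = _tri(a.nutrient_result("marketability"))
        for criterion in NUTRIENT_CRITERIA:
            row[criterion] = _tri(a.nutrient_result(criterion))
        for criterion in PROMOTION_CRITERIA:
            row[criterion] = _tri(a.promotion_result(criterion))
        rows.append(row)
    columns = (["product_id", "category", "age_bucket", "marketable",
                "nutrient_compliant", "promotion_compliant", "fop_required",
                "marketability"]
               + list(NUTRIENT_CRITERIA) + list(PROMOTION_CRITERIA))
    frame = pd.DataFrame(rows, columns=columns)
    for col in frame.columns:
        if col not in ("product_id", "category", "age_bucket"):
            frame[col] = frame[col].astype("boolean")
    return frame


def results_frame(assessments: Sequence[ProductAssessment]) -> pd.DataFrame:
    """Tidy long frame: one row per (product, criterion) rule result."""
    rows = []
    for a in assessments:
        for kind, results in (("nutrient", a.nutrient_results),
                              ("promotion", a.promotion_results)):
            for r in results:
                rows.append({
                    "product_id": a.product_id,
                    "category": a.category.value,
                    "kind": kind,
                    "criterion": r.criterion,
                    "applicable": r.applicable,
                    "passed": r.passed,
                    "observed": r.observed,
                    "threshold": r.threshold,
                    "direction": r.direction,
                    "basis": r.basis,
                    "note": r.note,
                })
    return pd.DataFrame(rows)


def compare_with_ledger(
    assessments: Sequence[ProductAssessment],
    ledger: pd.DataFrame,
) -> pd.DataFrame:
    """Cell-level mismatches between pipeline verdicts and a truth ledger.

    Compares every column present in both the verdict frame and the
    ledger (NA in either must match NA in the other). Returns an empty
    frame when the pipeline reproduces the ledger exactly.
    """
    verdicts = verdict_frame(assessments).set_index("product_id")
    truth = ledger.set_index("product_id")
    shared = [c for c in truth.columns if c in verdicts.columns]
    mismatches = []
    for col in shared:
        got = verdicts[col]
        want = truth[col]
        if col in ("category", "age_bucket"):
            bad = got.astype(object) != want.astype(object)
        else:
            got = got.astype("boolean")
            want = want.astype("boolean")
            bad = (got.isna() != want.isna()) | (
                got.notna() & want.notna() & (got != want)).fillna(False)
        for pid in verdicts.index[bad.to_numpy(dtype=bool)]:
            mismatches.append({
                "product_id": pid, "column": col,
                "pipeline": got.loc[pid], "ledger": want.loc[pid],
            })
    return pd.DataFrame(mismatches,
                        columns=["product_id", "column", "pipeline", "ledger"])
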