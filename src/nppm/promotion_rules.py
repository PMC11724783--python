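"""NPPM promotional requirements.

Promotion is assessed per product over eight criteria: absence of
nutrition/health/marketing claims, an appropriate lower age label
(>= 6 months), a statement supporting and protecting breastfeeding,
a "do not suck from the spout" warning on spouted packs, product-name
clarity (the name reflects the main ingredients), ingredient-list
completeness (proportions of the largest ingredient, water/stock and
fruit declared), preparation instructions where preparation is needed,
and the front-of-pack high-sugar flag where required. A product is
promotion-compliant only if it passes every applicable criterion.

Claim detection is lexicon-based over the free-text claims found on
pack; a manual adjudication column (``name_reflects_main_ingredients``)
always wins for name clarity, mirroring researcher consensus coding.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .ingestion import Category, LabelInfo, ProductRecord
from .nutrient_rules import RuleResult
from .sugar_profile import normalize_text

CLAIM_TYPES = ("nutrition", "health", "marketing")

#: Categories whose products require preparation instructions by default
#: (dry cereals to be reconstituted; meals needing heating).
DEFAULT_PREPARATION_CATEGORIES = ("Cereals", "Meals", "Ingredients")

PROMOTION_CRITERIA = (
    "claims", "age_label", "breastfeeding", "spout_warning",
    "name_clarity", "ingredient_list", "preparation_instructions",
    "fop_label",
)


class ClaimLexicon:
    """Claim patterns mapped to claim type (nutrition/health/marketing)."""

    def __init__(self, patterns: Sequence[tuple[str, str]]):
        seen: dict[str, str] = {}
        for pattern, ctype in patterns:
            key = normalize_text(pattern)
            if ctype not in CLAIM_TYPES:
                raise ValueError(f"unknown claim type {ctype!r} for {pattern!r}")
            if key and key not in seen:
                seen[key] = ctype
        self._patterns = list(seen.items())
        self._ordered = sorted(self._patterns, key=lambda pc: -len(pc[0]))

    def __len__(self) -> int:
        return len(self._patterns)

    def items(self) -> list[tuple[str, str]]:
        return list(self._patterns)

    def match(self, text: str) -> Optional[tuple[str, str]]:
        """(pattern, type) of the longest matching pattern, or None."""
        t = normalize_text(text)
        for pattern, ctype in self._ordered:
            if pattern in t:
                return pattern, ctype
        return None

    @classmethod
    def from_csv(cls, path: str | Path) -> "ClaimLexicon":
        with open(path, newline="") as fh:
            return cls._from_rows(csv.reader(fh))

    @classmethod
    def _from_rows(cls, rows: Iterable[Sequence[str]]) -> "ClaimLexicon":
        patterns = []
        for row in rows:
            if not row or row[0].strip().startswith("#"):
                continue
            if row[0].strip().lower() == "pattern":
                continue
            patterns.append((row[0].strip(), row[1].strip()))
        return cls(patterns)

    @classmethod
    def default(cls) -> "ClaimLexicon":
        global _DEFAULT_CLAIMS
        if _DEFAULT_CLAIMS is None:
            text = resources.files("nppm.data").joinpath(
                "claim_lexicon.csv").read_text()
            _DEFAULT_CLAIMS = cls._from_rows(csv.reader(text.splitlines()))
        return _DEFAULT_CLAIMS


_DEFAULT_CLAIMS: Optional[ClaimLexicon] = None
_FOOD_WORDS: Optional[frozenset] = None


def default_food_words() -> frozenset[str]:
    global _FOOD_WORDS
    if _FOOD_WORDS is None:
        text = resources.files("nppm.data").joinpath(
            "food_words.txt").read_text()
        _FOOD_WORDS = frozenset(
            line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#"))
    return _FOOD_WORDS


# ---------------------------------------------------------------------------
# Individual criteria
# ---------------------------------------------------------------------------

def claims_rule(label: LabelInfo,
                lexicon: Optional[ClaimLexicon] = None) -> RuleResult:
    """No nutrition, health or marketing claims are permitted."""
    lexicon = lexicon or ClaimLexicon.default()
    hits = []
    for text in label.claim_texts:
        m = lexicon.match(text)
        if m is not None:
            hits.append((text, m[1]))
    return RuleResult(
        criterion="claims", applicable=True, passed=not hits,
        observed=float(len(hits)), threshold=0.0, direction="le",
        note="; ".join(f"{t!r} [{c}]" for t, c in hits))


def age_label_rule(lower_age_months: Optional[int]) -> RuleResult:
    """Marketing from under six months (or with no age statement) fails."""
    if lower_age_months is None:
        return RuleResult(
            criterion="age_label", applicable=True, passed=False,
            note="no age recommendation found")
    return RuleResult(
        criterion="age_label", applicable=True,
        passed=lower_age_months >= 6, observed=float(lower_age_months),
        threshold=6.0, direction="ge")


def breastfeeding_statement_rule(label: LabelInfo) -> RuleResult:
    """An adequate statement supporting breastfeeding must be present."""
    passed = (label.has_breastfeeding_statement
              and label.breastfeeding_statement_adequate)
    note = ""
    if label.has_breastfeeding_statement and not passed:
        note = "statement present but inadequate"
    elif not label.has_breastfeeding_statement:
        note = "statement absent"
    return RuleResult(criterion="breastfeeding", applicable=True,
                      passed=passed, note=note)


def spout_warning_rule(p: ProductRecord) -> RuleResult:
    """Spouted packs must warn that children should not suck the spout."""
    if not p.label.has_spout:
        return RuleResult(criterion="spout_warning", applicable=False,
                          note="no spout")
    return RuleResult(criterion="spout_warning", applicable=True,
                      passed=p.label.has_spout_warning)


def name_clarity_rule(
    p: ProductRecord,
    food_words: Optional[frozenset[str]] = None,
    top_k: int = 3,
) -> RuleResult:
    """The product name must reflect the main ingredients.

    Heuristic: every food-noun token of the name (token found in the
    food-word vocabulary) must appear among the tokens of the top-`top_k`
    ingredients. A manual adjudication value on the label takes
    precedence when present.
    """
    if p.label.name_reflects_main_ingredients is not None:
        return RuleResult(
            criterion="name_clarity", applicable=True,
            passed=p.label.name_reflects_main_ingredients,
            note="manual adjudication")
    if not p.ingredients:
        return RuleResult(criterion="name_clarity", applicable=True,
                          passed=None, note="empty ingredient list")
    food_words = food_words if food_words is not None else default_food_words()
    name_tokens = normalize_text(p.name).split()
    top_tokens = {
        tok
        for name, _ in p.ingredients[:top_k]
        for tok in normalize_text(name).split()
    }
    food_tokens = [t for t in name_tokens if t in food_words]
    missing = [t for t in food_tokens if t not in top_tokens]
    return RuleResult(
        criterion="name_clarity", applicable=True, passed=not missing,
        note="" if not missing else
        "name tokens not among main ingredients: " + ", ".join(missing))


def ingredient_list_rule(label: LabelInfo) -> RuleResult:
    """Proportions of the largest ingredient, water/stock and fruit must
    be declared where relevant."""
    return RuleResult(criterion="ingredient_list", applicable=True,
                      passed=label.ingredient_proportions_declared)


def preparation_instructions_rule(
    label: LabelInfo,
    category: Category | str,
    required_categories: Sequence[str] = DEFAULT_PREPARATION_CATEGORIES,
) -> RuleResult:
    """Preparation instructions are required where preparation is needed
    (config-driven applicability per category)."""
    cat = category.value if isinstance(category, Category) else str(category)
    if cat not in required_categories:
        return RuleResult(criterion="preparation_instructions",
                          applicable=False, note="ready to eat")
    return RuleResult(criterion="preparation_instructions", applicable=True,
                      passed=label.has_preparation_instructions)


def fop_label_rule(label: LabelInfo, required: bool) -> RuleResult:
    """The front-of-pack high-sugar flag must be present when required."""
    if not required:
        return RuleResult(criterion="fop_label", applicable=False,
                          note="flag not required")
    return RuleResult(criterion="fop_label", applicable=True,
                      passed=label.has_fop_sugar_flag)


# ---------------------------------------------------------------------------
# Combined promotion verdict
# ---------------------------------------------------------------------------

def assess_promotion(
    p: ProductRecord,
    claim_lexicon: Optional[ClaimLexicon] = None,
    fop_required: bool = False,
    food_words: Optional[frozenset[str]] = None,
    preparation_categories: Sequence[str] = DEFAULT_PREPARATION_CATEGORIES,
    strict_incomplete: bool = False,
) -> tuple[list[RuleResult], bool]:
    """Evaluate all promotion criteria; returns (results, compliant).

    The verdict is the conjunction of the applicable, assessable
    results (order-independent); with `strict_incomplete` a
    not-assessable result also fails the product.
    """
    results = [
        claims_rule(p.label, claim_lexicon),
        age_label_rule(p.lower_age_months),
        breastfeeding_statement_rule(p.label),
        spout_warning_rule(p),
        name_clarity_rule(p, food_words),
        ingredient_list_rule(p.label),
        preparation_instructions_rule(p.label, p.category,
                                      preparation_categories),
        fop_label_rule(p.label, fop_required),
    ]
    applicable = [r for r in results if r.applicable]
    if any(r.passed is False for r in applicable):
        compliant = False
    elif strict_incomplete and any(r.passed is None for r in applicable):
        compliant = False
    else:
        compliant = True
    return results, compliant
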