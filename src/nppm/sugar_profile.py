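"""Sugar-source classification and sugar-based rules.

The NPPM distinguishes five sugar classes: sugars *added* during
processing, *free* sugars naturally present in honey, syrups, juices
and fruit concentrates, *liberated* sugars released from plant cells by
processing (pureeing), and intrinsic sugars still inside plant cell
walls (*plant_intrinsic*) or naturally present in milk
(*milk_intrinsic*, largely lactose). Added and free sugars are
prohibited in foods for infants and young children; liberated sugars
are reported (prohibition is a configurable strict mode); intrinsic
sugars are allowed.

Ingredient strings are matched against a user-extensible lexicon of
term patterns, case-insensitively, longest pattern first.

This module also expresses total sugar as a percentage of energy
(4 kcal/g carbohydrate) and determines when a front-of-pack (FOP)
high-sugar flag is required: fruit/vegetable products and cereals
exceeding 30 % of energy from sugar, dairy exceeding 40 % (strict
inequality, per the "exceeding" wording).
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .ingestion import Category, ProductRecord
from .nutrient_rules import (KCAL_PER_G_CARBOHYDRATE, RuleResult, RuleTable)

SUGAR_CLASSES = ("added", "free", "liberated", "milk_intrinsic",
                 "plant_intrinsic")

#: Classes whose presence violates the added-sugar prohibition.
PROHIBITED_CLASSES = ("added", "free")


def normalize_text(s: str) -> str:
    """Lower-case, strip accents and collapse whitespace."""
    s = unicodedata.normalize("NFKD", s)
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    return re.sub(r"\s+", " ", s.strip().lower())


class SugarLexicon:
    """Term patterns mapped to sugar classes.

    Matching is case-insensitive substring search on normalized text,
    longest pattern first; ties are broken by lexicon order. Every
    pattern maps to exactly one class.
    """

    def __init__(self, patterns: Sequence[tuple[str, str]]):
        seen: dict[str, str] = {}
        for pattern, cls in patterns:
            key = normalize_text(pattern)
            if cls not in SUGAR_CLASSES:
                raise ValueError(f"unknown sugar class {cls!r} for {pattern!r}")
            if key in seen and seen[key] != cls:
                raise ValueError(f"pattern {pattern!r} mapped to two classes")
            if key and key not in seen:
                seen[key] = cls
        self._patterns = list(seen.items())
        # longest first; python sort is stable so file order breaks ties
        self._ordered = sorted(self._patterns, key=lambda pc: -len(pc[0]))

    def __len__(self) -> int:
        return len(self._patterns)

    def items(self) -> list[tuple[str, str]]:
        return list(self._patterns)

    def classify(self, ingredient: str) -> Optional[str]:
        """Sugar class of the first (longest) matching pattern, or None."""
        text = normalize_text(ingredient)
        for pattern, cls in self._ordered:
            if pattern in text:
                return cls
        return None

    # -- file format (two-column CSV: pattern, class) ---------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "SugarLexicon":
        with open(path, newline="") as fh:
            return cls._from_rows(csv.reader(fh))

    @classmethod
    def _from_rows(cls, rows: Iterable[Sequence[str]]) -> "SugarLexicon":
        patterns = []
        for row in rows:
            if not row or row[0].strip().startswith("#"):
                continue
            if row[0].strip().lower() == "pattern":  # header
                continue
            patterns.append((row[0].strip(), row[1].strip()))
        return cls(patterns)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["pattern", "class"])
            writer.writerows(self._patterns)

    @classmethod
    def default(cls) -> "SugarLexicon":
        global _DEFAULT_LEXICON
        if _DEFAULT_LEXICON is None:
            text = resources.files("nppm.data").joinpath(
                "sugar_lexicon.csv").read_text()
            _DEFAULT_LEXICON = cls._from_rows(csv.reader(text.splitlines()))
        return _DEFAULT_LEXICON


_DEFAULT_LEXICON: Optional["SugarLexicon"] = None


@dataclass
class SugarProfile:
    """Sugar-related findings for one product."""

    pct_energy_from_sugar: Optional[float]
    has_added_or_prohibited_sugar: bool
    matched_terms: list[tuple[str, str]] = field(default_factory=list)
    fop_flag_required: bool = False


def pct_energy_from_sugar(
    sugar_g_100g: Optional[float],
    energy_kcal_100g: Optional[float],
    kcal_per_g: float = KCAL_PER_G_CARBOHYDRATE,
) -> Optional[float]:
    """Percent of energy from total sugar; None when not assessable."""
    if sugar_g_100g is None or energy_kcal_100g is None:
        return None
    if energy_kcal_100g <= 0:
        return None
    return sugar_g_100g * kcal_per_g / energy_kcal_100g * 100.0


def classify_ingredients(
    ingredients: Sequence[tuple[str, Optional[float]]] | Sequence[str],
    lexicon: Optional[SugarLexicon] = None,
) -> list[tuple[str, str]]:
    """Match each ingredient against the lexicon.

    Accepts either bare ingredient strings or (name, percent) pairs.
    Unmatched ingredients carry no sugar class and are omitted.
    """
    lexicon = lexicon or SugarLexicon.default()
    out: list[tuple[str, str]] = []
    for item in ingredients:
        name = item[0] if isinstance(item, (tuple, list)) else item
        cls = lexicon.classify(name)
        if cls is not None:
            out.append((name, cls))
    return out


def added_sugar_rule(
    classes: Sequence[tuple[str, str]],
    product: Optional[ProductRecord] = None,
    rules: Optional[RuleTable] = None,
    prohibit_liberated: bool = False,
) -> RuleResult:
    """Prohibition of added and free sugars.

    Fails iff any classified ingredient is of a prohibited class.
    Liberated sugars are report-only by default (`prohibit_liberated`
    enables the strict mode). Applies to every marketable category.
    """
    if product is not None:
        rules = rules or RuleTable.default()
        if product.category.value in rules.non_marketable:
            return RuleResult(criterion="added_sugar", applicable=False,
                              note="not evaluated: non-marketable category")
    prohibited = set(PROHIBITED_CLASSES)
    if prohibit_liberated:
        prohibited.add("liberated")
    hits = [(name, cls) for name, cls in classes if cls in prohibited]
    reported = [(name, cls) for name, cls in classes
                if cls == "liberated" and not prohibit_liberated]
    note = ""
    if hits:
        note = "prohibited sugar source(s): " + "; ".join(
            f"{n} [{c}]" for n, c in hits)
    elif reported:
        note = "liberated sugar source(s) reported: " + "; ".join(
            n for n, _ in reported)
    return RuleResult(
        criterion="added_sugar", applicable=True, passed=not hits,
        observed=float(len(hits)), threshold=0.0, direction="le",
        basis="count", note=note)


def fop_flag_required(
    category: Category | str,
    pct_energy: Optional[float],
    rules: Optional[RuleTable] = None,
) -> bool:
    """Front-of-pack high-sugar flag requirement.

    True iff the category carries a FOP threshold (fruit/vegetable and
    cereals 30 %E, dairy 40 %E by default) and the percent of energy
    from sugar strictly exceeds it.
    """
    rules = rules or RuleTable.default()
    cat = category.value if isinstance(category, Category) else str(category)
    threshold = rules.fop_thresholds.get(cat)
    if threshold is None or pct_energy is None:
        return False
    return pct_energy > threshold


def profile_product(
    p: ProductRecord,
    lexicon: Optional[SugarLexicon] = None,
    rules: Optional[RuleTable] = None,
) -> SugarProfile:
    """Compute the full sugar profile of one product."""
    rules = rules or RuleTable.default()
    matched = classify_ingredients(p.ingredients, lexicon)
    pct = pct_energy_from_sugar(
        p.total_sugar_g_100g, p.energy_kcal_100g,
        kcal_per_g=rules.kcal_per_g_carbohydrate)
    return SugarProfile(
        pct_energy_from_sugar=pct,
        has_added_or_prohibited_sugar=any(
            cls in PROHIBITED_CLASSES for _, cls in matched),
        matched_terms=matched,
        fop_flag_required=fop_flag_required(p.category, pct, rules),
    )
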