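"""NPPM nutrient-composition criteria.

The criterion matrix (category x criterion -> threshold, direction,
basis, applicability) is an editable rule table loaded from YAML; the
packaged default reproduces the WHO NPPM composition criteria:

* energy: dry cereals/starches >= 80 kcal/100 g as prepared; dairy,
  fruit/vegetable products and meals >= 60 kcal/100 g; snacks
  <= 50 kcal per serving;
* protein: dry cereals containing milk <= 5.5 g/100 kcal; savoury
  meals >= 3 g/100 kcal, with an elevated (configurable) minimum for
  meals containing meat, poultry or fish;
* fat: <= 4.5 g/100 kcal, <= 6 g/100 kcal for meat/poultry/fish meals;
* total sugar: <= 15 % of energy for meals and non-fruit snacks;
* salt: <= 0.125 g/100 kcal, <= 0.25 g/100 kcal with cheese;
* marketability: confectionery and drinks must not be marketed as
  foods for infants and young children at all.

All printed thresholds are inclusive at the boundary: a product at
exactly the threshold value passes. A product is non-compliant overall
if it fails any single applicable criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .ingestion import Category, ProductRecord

#: kcal per gram of carbohydrate, used to express sugar as % of energy.
KCAL_PER_G_CARBOHYDRATE = 4.0

NUTRIENT_FIELDS = {
    "protein": "protein_g_100g",
    "fat": "fat_g_100g",
    "salt": "salt_g_100g",
    "sugar_pct": "total_sugar_g_100g",
}

VALID_BASES = (
    "kcal_100g", "kcal_100g_prepared", "kcal_per_serving",
    "g_100kcal", "pct_energy", "pct_fruit", "pct_water",
)


def per_100kcal(value_g_100g: Optional[float],
                energy_kcal_100g: Optional[float]) -> Optional[float]:
    """Convert a per-100 g nutrient mass to the per-100 kcal basis.

    Returns ``None`` (not assessable) when either input is missing or
    energy is non-positive.
    """
    if value_g_100g is None or energy_kcal_100g is None:
        return None
    if energy_kcal_100g <= 0:
        return None
    return value_g_100g * 100.0 / energy_kcal_100g


@dataclass
class RuleResult:
    """Outcome of one criterion applied to one product.

    ``applicable=False`` results are vacuous: they never enter a
    compliance denominator. ``passed=None`` with ``applicable=True``
    means the criterion could not be assessed (missing input).
    """

    criterion: str
    applicable: bool
    passed: Optional[bool] = None
    observed: Optional[float] = None
    basis: Optional[str] = None
    threshold: Optional[float] = None
    direction: Optional[str] = None
    note: str = ""

    @property
    def counts_as_fail(self) -> bool:
        return self.applicable and self.passed is False


@dataclass
class ProductAssessment:
    """All rule results for one product plus the overall verdicts."""

    product_id: str
    category: Category
    lower_age_months: Optional[int] = None
    marketable: bool = True
    nutrient_results: list[RuleResult] = field(default_factory=list)
    promotion_results: list[RuleResult] = field(default_factory=list)
    nutrient_compliant: Optional[bool] = None
    promotion_compliant: Optional[bool] = None
    fop_flag_required: bool = False
    notes: list[str] = field(default_factory=list)

    def nutrient_result(self, criterion: str) -> Optional[RuleResult]:
        for r in self.nutrient_results:
            if r.criterion == criterion:
                return r
        return None

    def promotion_result(self, criterion: str) -> Optional[RuleResult]:
        for r in self.promotion_results:
            if r.criterion == criterion:
                return r
        return None


@dataclass(frozen=True)
class RuleEntry:
    """One cell of the criterion matrix."""

    criterion: str
    categories: tuple[str, ...]
    basis: str
    direction: str          # "ge" or "le"
    threshold: Optional[float]
    condition: Optional[str] = None   # subcategory flag, optionally "not <flag>"
    applicable: bool = True
    note: str = ""

    def matches(self, product: ProductRecord) -> bool:
        if product.category.value not in self.categories:
            return False
        return self.condition_holds(product)

    def condition_holds(self, product: ProductRecord) -> bool:
        if self.condition is None:
            return True
        cond = self.condition.strip()
        if cond.startswith("not "):
            return not product.flag(cond[4:].strip())
        return product.flag(cond)


class RuleTable:
    """The configurable NPPM criterion matrix.

    Lookup precedence: a condition-specific entry beats the generic
    (condition-free) entry for the same criterion and category, so that
    e.g. the cheese salt allowance overrides the default salt limit.
    """

    def __init__(
        self,
        entries: Sequence[RuleEntry],
        kcal_per_g_carbohydrate: float = KCAL_PER_G_CARBOHYDRATE,
        non_marketable: Sequence[str] = ("Confectionery", "Drinks"),
        incomplete_policy: str = "assess_available",
        fop_thresholds: Optional[dict[str, float]] = None,
    ):
        for e in entries:
            if e.direction not in ("ge", "le"):
                raise ValueError(f"bad direction {e.direction!r} in {e.criterion}")
            if e.basis not in VALID_BASES:
                raise ValueError(f"bad basis {e.basis!r} in {e.criterion}")
            if e.threshold is not None and e.threshold < 0:
                raise ValueError(f"negative threshold in {e.criterion}")
        if incomplete_policy not in ("assess_available", "strict"):
            raise ValueError(f"unknown incomplete policy {incomplete_policy!r}")
        self.entries = list(entries)
        self.kcal_per_g_carbohydrate = float(kcal_per_g_carbohydrate)
        self.non_marketable = tuple(non_marketable)
        self.incomplete_policy = incomplete_policy
        self.fop_thresholds = dict(
            fop_thresholds
            if fop_thresholds is not None
            else {"FruitVeg": 30.0, "Cereals": 30.0, "Dairy": 40.0}
        )
        self._check_unambiguous()

    def _check_unambiguous(self) -> None:
        # For every criterion and category, at most one generic entry.
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            if e.condition is not None:
                continue
            for cat in e.categories:
                key = (e.criterion, cat)
                if key in seen:
                    raise ValueError(
                        f"ambiguous rule table: two generic entries for {key}")
                seen.add(key)

    def lookup(self, criterion: str, product: ProductRecord) -> Optional[RuleEntry]:
        """Return the single entry governing (criterion, product), or None."""
        # Conditional entries beat the generic entry; among conditional
        # matches the first in table order wins (most specific first).
        for e in self.entries:
            if (e.criterion == criterion and e.condition is not None
                    and e.matches(product)):
                return e
        for e in self.entries:
            if e.criterion == criterion and e.condition is None and e.matches(product):
                return e
        return None

    def criteria(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.criterion not in out:
                out.append(e.criterion)
        return out

    # -- serialization ----------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: dict) -> "RuleTable":
        entries = [
            RuleEntry(
                criterion=item["criterion"],
                categories=tuple(item["categories"]),
                basis=item["basis"],
                direction=item["direction"],
                threshold=(None if item.get("threshold") is None
                           else float(item["threshold"])),
                condition=item.get("condition"),
                applicable=bool(item.get("applicable", True)),
                note=item.get("note", ""),
            )
            for item in cfg.get("criteria", [])
        ]
        return cls(
            entries,
            kcal_per_g_carbohydrate=cfg.get(
                "kcal_per_g_carbohydrate", KCAL_PER_G_CARBOHYDRATE),
            non_marketable=tuple(cfg.get(
                "non_marketable", ("Confectionery", "Drinks"))),
            incomplete_policy=cfg.get("incomplete_policy", "assess_available"),
            fop_thresholds=cfg.get("fop_pct_energy_thresholds"),
        )

    def to_dict(self) -> dict:
        return {
            "kcal_per_g_carbohydrate": self.kcal_per_g_carbohydrate,
            "non_marketable": list(self.non_marketable),
            "incomplete_policy": self.incomplete_policy,
            "fop_pct_energy_thresholds": dict(self.fop_thresholds),
            "criteria": [
                {
                    "criterion": e.criterion,
                    "categories": list(e.categories),
                    "basis": e.basis,
                    "direction": e.direction,
                    "threshold": e.threshold,
                    **({"condition": e.condition} if e.condition else {}),
                    **({} if e.applicable else {"applicable": False}),
                    **({"note": e.note} if e.note else {}),
                }
                for e in self.entries
            ],
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def default(cls) -> "RuleTable":
        """The packaged WHO-NPPM default criterion matrix (shared
        instance; build from YAML explicitly if you need to mutate)."""
        global _DEFAULT_TABLE
        if _DEFAULT_TABLE is None:
            text = resources.files("nppm.data").joinpath(
                "rules.yaml").read_text()
            _DEFAULT_TABLE = cls.from_dict(yaml.safe_load(text))
        return _DEFAULT_TABLE


_DEFAULT_TABLE: Optional[RuleTable] = None


# ---------------------------------------------------------------------------
# Observed values per basis
# ---------------------------------------------------------------------------

def observed_value(
    product: ProductRecord,
    entry: RuleEntry,
    rules: RuleTable,
) -> tuple[Optional[float], str]:
    """Compute the product's value on the entry's basis.

    Returns (value, note); value is None when not assessable.
    """
    p = product
    basis = entry.basis
    if basis == "kcal_100g":
        return p.energy_kcal_100g, ""
    if basis == "kcal_100g_prepared":
        if p.prepared_energy_kcal_100g is not None:
            return p.prepared_energy_kcal_100g, ""
        # Fall back to the dry label value, flagged.
        return (p.energy_kcal_100g,
                "assessed on dry label energy (prepared value missing)")
    if basis == "kcal_per_serving":
        if p.energy_kcal_100g is None or p.serving_g is None:
            return None, "serving size or energy missing"
        return p.energy_kcal_100g * p.serving_g / 100.0, ""
    if basis == "g_100kcal":
        nutrient = NUTRIENT_FIELDS[entry.criterion]
        return per_100kcal(getattr(p, nutrient), p.energy_kcal_100g), ""
    if basis == "pct_energy":
        if (p.total_sugar_g_100g is None or p.energy_kcal_100g is None
                or p.energy_kcal_100g <= 0):
            return None, "energy or sugar missing"
        return (p.total_sugar_g_100g * rules.kcal_per_g_carbohydrate
                / p.energy_kcal_100g * 100.0), ""
    # pct_fruit / pct_water: label inputs not modelled; not assessable.
    return None, f"basis {basis} not assessable from the nutrient panel"


def _evaluate(product: ProductRecord, criterion: str,
              rules: RuleTable) -> RuleResult:
    entry = rules.lookup(criterion, product)
    if entry is None or not entry.applicable or entry.threshold is None:
        note = "" if entry is None else entry.note
        return RuleResult(criterion=criterion, applicable=False, note=note)
    value, note = observed_value(product, entry, rules)
    if value is None:
        return RuleResult(
            criterion=criterion, applicable=True, passed=None,
            basis=entry.basis, threshold=entry.threshold,
            direction=entry.direction, note=note or "not assessable")
    passed = value >= entry.threshold if entry.direction == "ge" \
        else value <= entry.threshold
    return RuleResult(
        criterion=criterion, applicable=True, passed=passed, observed=value,
        basis=entry.basis, threshold=entry.threshold,
        direction=entry.direction, note=note)


# ---------------------------------------------------------------------------
# Individual criteria
# ---------------------------------------------------------------------------

def marketability_rule(p: ProductRecord,
                       rules: Optional[RuleTable] = None) -> RuleResult:
    """Confectionery and drinks must not be marketed as FIYC at all."""
    rules = rules or RuleTable.default()
    marketable = p.category.value not in rules.non_marketable
    return RuleResult(
        criterion="marketability", applicable=True, passed=marketable,
        note="" if marketable else
        f"{p.category.value} must not be marketed as food for infants "
        "and young children")


def energy_rule(p: ProductRecord, rules: Optional[RuleTable] = None) -> RuleResult:
    rules = rules or RuleTable.default()
    return _evaluate(p, "energy", rules)


def protein_rule(p: ProductRecord, rules: Optional[RuleTable] = None) -> RuleResult:
    rules = rules or RuleTable.default()
    return _evaluate(p, "protein", rules)


def fat_rule(p: ProductRecord, rules: Optional[RuleTable] = None) -> RuleResult:
    rules = rules or RuleTable.default()
    return _evaluate(p, "fat", rules)


def salt_rule(p: ProductRecord, rules: Optional[RuleTable] = None) -> RuleResult:
    rules = rules or RuleTable.default()
    return _evaluate(p, "salt", rules)


def sugar_pct_rule(
    p: ProductRecord,
    pct_energy: Optional[float] = None,
    rules: Optional[RuleTable] = None,
) -> RuleResult:
    """Total sugar <= 15 % of energy for meals and non-fruit snacks.

    `pct_energy` may be supplied pre-computed (from the sugar profile);
    otherwise it is derived from the nutrient panel.
    """
    rules = rules or RuleTable.default()
    entry = rules.lookup("sugar_pct", p)
    if entry is None or not entry.applicable or entry.threshold is None:
        return RuleResult(criterion="sugar_pct", applicable=False)
    if pct_energy is None:
        pct_energy, _ = observed_value(p, entry, rules)
    if pct_energy is None:
        return RuleResult(
            criterion="sugar_pct", applicable=True, passed=None,
            basis=entry.basis, threshold=entry.threshold,
            direction=entry.direction, note="not assessable")
    return RuleResult(
        criterion="sugar_pct", applicable=True,
        passed=pct_energy <= entry.threshold, observed=pct_energy,
        basis=entry.basis, threshold=entry.threshold,
        direction=entry.direction)


NUTRIENT_CRITERIA = ("energy", "protein", "fat", "sugar_pct", "added_sugar",
                     "salt", "fruit_content", "added_water")


def assess_nutrients(
    p: ProductRecord,
    rules: Optional[RuleTable] = None,
    sugar=None,
) -> ProductAssessment:
    """Run every nutrient criterion and form the overall nutrient verdict.

    `sugar` is the product's :class:`~nppm.sugar_profile.SugarProfile`;
    if omitted it is computed with the default lexicon. The overall
    verdict is the conjunction over applicable, assessable results, and
    is False outright for non-marketable categories, whose nutrient
    panel is not evaluated.
    """
    from . import sugar_profile as sp

    rules = rules or RuleTable.default()
    if sugar is None:
        sugar = sp.profile_product(p, rules=rules)

    assessment = ProductAssessment(
        product_id=p.product_id, category=p.category,
        lower_age_months=p.lower_age_months,
        fop_flag_required=sugar.fop_flag_required,
    )
    market = marketability_rule(p, rules)
    assessment.nutrient_results.append(market)
    assessment.marketable = bool(market.passed)
    if not assessment.marketable:
        # Table-2 note practice: nutrient panels of non-marketable
        # products are not evaluated.
        for criterion in NUTRIENT_CRITERIA:
            assessment.nutrient_results.append(RuleResult(
                criterion=criterion, applicable=False,
                note="not evaluated: non-marketable category"))
        assessment.nutrient_compliant = False
        return assessment

    for criterion in NUTRIENT_CRITERIA:
        if criterion == "sugar_pct":
            result = sugar_pct_rule(p, sugar.pct_energy_from_sugar, rules)
        elif criterion == "added_sugar":
            result = sp.added_sugar_rule(sugar.matched_terms, product=p,
                                         rules=rules)
        else:
            result = _evaluate(p, criterion, rules)
        assessment.nutrient_results.append(result)

    applicable = [r for r in assessment.nutrient_results if r.applicable]
    incomplete = [r for r in applicable if r.passed is None]
    if incomplete:
        assessment.notes.append(
            "incomplete: " + ", ".join(r.criterion for r in incomplete))
    if any(r.passed is False for r in applicable):
        assessment.nutrient_compliant = False
    elif incomplete and rules.incomplete_policy == "strict":
        assessment.nutrient_compliant = False
    else:
        assessment.nutrient_compliant = True
    return assessment
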