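"""Reading, validation and writing of product tables.

The canonical CSV schema has one row per product with these columns
(UTF-8, comma separated, RFC 4180 quoting):

``product_id, brand, name, category, subcategory_flags, age_label,
energy_kcal_100g, prepared_energy_kcal_100g, protein_g_100g, fat_g_100g,
total_sugar_g_100g, salt_g_100g, sodium_mg_100g, serving_g, ingredients,
claim_texts, has_breastfeeding_statement, breastfeeding_statement_adequate,
has_preparation_instructions, has_spout, has_spout_warning,
has_fop_sugar_flag, name_reflects_main_ingredients,
ingredient_proportions_declared``

* ``subcategory_flags`` — semicolon-separated flag tokens
  (e.g. ``is_dry_cereal;contains_milk``).
* ``ingredients`` — pipe-separated ``name`` or ``name:percent`` entries,
  in pack order (descending weight).
* ``claim_texts`` — pipe-separated free-text claims found on pack.
* Decimal commas are accepted and normalised to decimal points.
* ``sodium_mg_100g`` is an optional alternative to ``salt_g_100g``;
  it is converted as salt g = sodium mg x 2.5 / 1000.

Rows that cannot be validated are reported in an error ledger (with row
number and reason) rather than silently dropped.
"""

from __future__ import annotations

import re
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator


class Category(str, Enum):
    """The eight NPPM product categories."""

    CEREALS = "Cereals"
    DAIRY = "Dairy"
    FRUIT_VEG = "FruitVeg"
    MEALS = "Meals"
    SNACKS = "Snacks"
    INGREDIENTS = "Ingredients"
    CONFECTIONERY = "Confectionery"
    DRINKS = "Drinks"


#: Long-form names as they appear in NPPM templates, mapped to the enum.
CATEGORY_ALIASES = {
    "cereals": Category.CEREALS,
    "dry cereals": Category.CEREALS,
    "dry cereals and starches": Category.CEREALS,
    "dairy": Category.DAIRY,
    "fruitveg": Category.FRUIT_VEG,
    "fruit & vegetable": Category.FRUIT_VEG,
    "fruit & vegetables": Category.FRUIT_VEG,
    "fruit and vegetables": Category.FRUIT_VEG,
    "meals": Category.MEALS,
    "meals and meal components": Category.MEALS,
    "snacks": Category.SNACKS,
    "snacks and finger foods": Category.SNACKS,
    "ingredients": Category.INGREDIENTS,
    "confectionery": Category.CONFECTIONERY,
    "confectionary": Category.CONFECTIONERY,
    "drinks": Category.DRINKS,
}

SUBCATEGORY_FLAGS = (
    "is_dry_cereal",
    "contains_milk",
    "is_savoury_meal",
    "contains_meat_poultry_fish",
    "contains_cheese",
    "is_fruit_based_snack",
    "is_puree_with_spout",
)


class AgeBucket(str, Enum):
    """Lower-age-recommendation bands used for reporting."""

    UNDER6 = "under6"
    M6TO9 = "m6to9"
    M10TO11 = "m10to11"
    M12PLUS = "m12plus"


class LabelInfo(BaseModel):
    """Label and packaging facts relevant to the promotional criteria."""

    model_config = ConfigDict(frozen=False)

    claim_texts: list[str] = Field(default_factory=list)
    has_breastfeeding_statement: bool = False
    breastfeeding_statement_adequate: bool = False
    has_preparation_instructions: bool = False
    has_spout: bool = False
    has_spout_warning: bool = False
    has_fop_sugar_flag: bool = False
    name_reflects_main_ingredients: Optional[bool] = None
    ingredient_proportions_declared: bool = False


class ProductRecord(BaseModel):
    """One labelled product, nutrient declaration per 100 g as sold."""

    product_id: str
    brand: str = ""
    name: str = ""
    category: Category
    subcategory_flags: frozenset[str] = frozenset()
    lower_age_months: Optional[int] = Field(default=None, ge=0, le=48)
    energy_kcal_100g: Optional[float] = Field(default=None, ge=0)
    prepared_energy_kcal_100g: Optional[float] = Field(default=None, ge=0)
    protein_g_100g: Optional[float] = Field(default=None, ge=0, le=100)
    fat_g_100g: Optional[float] = Field(default=None, ge=0, le=100)
    total_sugar_g_100g: Optional[float] = Field(default=None, ge=0, le=100)
    salt_g_100g: Optional[float] = Field(default=None, ge=0, le=100)
    serving_g: Optional[float] = Field(default=None, gt=0)
    ingredients: list[tuple[str, Optional[float]]] = Field(default_factory=list)
    label: LabelInfo = Field(default_factory=LabelInfo)

    @field_validator("subcategory_flags", mode="before")
    @classmethod
    def _check_flags(cls, v):
        flags = frozenset(v)
        unknown = flags - set(SUBCATEGORY_FLAGS)
        if unknown:
            raise ValueError(f"unknown subcategory flags: {sorted(unknown)}")
        return flags

    def flag(self, name: str) -> bool:
        return name in self.subcategory_flags


# ---------------------------------------------------------------------------
# Age parsing
# ---------------------------------------------------------------------------

_UNIT = r"(months?|mths?|mos?|m\b|years?|yrs?|y\b)"
_RANGE_RE = re.compile(r"(\d+)\s*(?:[-–—]|to)\s*(\d+)\s*\+?\s*" + _UNIT, re.I)
_SINGLE_RE = re.compile(r"(\d+)\s*\+?\s*" + _UNIT, re.I)


def parse_lower_age(label_text: Optional[str]) -> Optional[int]:
    """Extract the minimum marketed age in months from a label string.

    Ranges ("12-24 months") yield their lower bound; year units are
    converted to months. Returns ``None`` when no age token is found.
    """
    if label_text is None:
        return None
    text = str(label_text).strip()
    if not text:
        return None
    m = _RANGE_RE.search(text) or _SINGLE_RE.search(text)
    if m is None:
        return None
    value = int(m.group(1))
    unit = m.group(m.lastindex).lower()
    if unit.startswith("y"):
        value *= 12
    return value


def bucket_age(months: Optional[int]) -> Optional[AgeBucket]:
    """Map an age in months onto the reporting bands (total, monotone)."""
    if months is None:
        return None
    if months < 6:
        return AgeBucket.UNDER6
    if months <= 9:
        return AgeBucket.M6TO9
    if months <= 11:
        return AgeBucket.M10TO11
    return AgeBucket.M12PLUS


# ---------------------------------------------------------------------------
# CSV reading
# ---------------------------------------------------------------------------

CANONICAL_COLUMNS = [
    "product_id", "brand", "name", "category", "subcategory_flags",
    "age_label", "energy_kcal_100g", "prepared_energy_kcal_100g",
    "protein_g_100g", "fat_g_100g", "total_sugar_g_100g", "salt_g_100g",
    "sodium_mg_100g", "serving_g", "ingredients", "claim_texts",
    "has_breastfeeding_statement", "breastfeeding_statement_adequate",
    "has_preparation_instructions", "has_spout", "has_spout_warning",
    "has_fop_sugar_flag", "name_reflects_main_ingredients",
    "ingredient_proportions_declared",
]

_BOOL_COLUMNS = [
    "has_breastfeeding_statement", "breastfeeding_statement_adequate",
    "has_preparation_instructions", "has_spout", "has_spout_warning",
    "has_fop_sugar_flag", "ingredient_proportions_declared",
]

_DECIMAL_COMMA_RE = re.compile(r"^-?\d+,\d+$")

SODIUM_TO_SALT = 2.5 / 1000.0  # salt g per sodium mg


def _parse_float(raw: str, column: str) -> Optional[float]:
    s = (raw or "").strip()
    if not s:
        return None
    if _DECIMAL_COMMA_RE.match(s):
        s = s.replace(",", ".")
    try:
        value = float(s)
    except ValueError as exc:
        raise ValueError(f"unparseable number in {column}: {raw!r}") from exc
    return value


def _parse_bool(raw: str) -> Optional[bool]:
    s = (raw or "").strip().lower()
    if not s:
        return None
    if s in ("true", "1", "yes", "y"):
        return True
    if s in ("false", "0", "no", "n"):
        return False
    raise ValueError(f"unparseable boolean: {raw!r}")


def parse_category(raw: str) -> Category:
    s = (raw or "").strip()
    key = re.sub(r"\s+", " ", s.lower())
    if key in CATEGORY_ALIASES:
        return CATEGORY_ALIASES[key]
    raise ValueError(f"unknown category: {raw!r}")


def _parse_ingredients(raw: str) -> list[tuple[str, Optional[float]]]:
    out: list[tuple[str, Optional[float]]] = []
    for part in (raw or "").split("|"):
        part = part.strip()
        if not part:
            continue
        name, pct = part, None
        if ":" in part:
            head, tail = part.rsplit(":", 1)
            try:
                pct = float(tail.strip().replace(",", "."))
                name = head.strip()
            except ValueError:
                pct = None
        out.append((name, pct))
    return out


def _row_to_record(row: dict) -> tuple[ProductRecord, list[str]]:
    """Build one validated record; returns (record, warning messages)."""
    warnings: list[str] = []
    category = parse_category(row.get("category", ""))

    flags = frozenset(
        tok.strip()
        for tok in (row.get("subcategory_flags") or "").split(";")
        if tok.strip()
    )

    age_label = (row.get("age_label") or "").strip()
    age = parse_lower_age(age_label)
    if age_label and age is None:
        warnings.append(f"unparseable age label {age_label!r}; age set missing")

    nutrients = {}
    for col in ("energy_kcal_100g", "prepared_energy_kcal_100g",
                "protein_g_100g", "fat_g_100g", "total_sugar_g_100g",
                "salt_g_100g", "serving_g"):
        value = _parse_float(row.get(col, ""), col)
        if value is not None and value < 0:
            raise ValueError(f"negative value in {col}: {value}")
        nutrients[col] = value
    if nutrients["salt_g_100g"] is None:
        sodium = _parse_float(row.get("sodium_mg_100g", ""), "sodium_mg_100g")
        if sodium is not None:
            if sodium < 0:
                raise ValueError(f"negative value in sodium_mg_100g: {sodium}")
            nutrients["salt_g_100g"] = sodium * SODIUM_TO_SALT

    label = LabelInfo(
        claim_texts=[c.strip() for c in (row.get("claim_texts") or "").split("|")
                     if c.strip()],
        name_reflects_main_ingredients=_parse_bool(
            row.get("name_reflects_main_ingredients", "")),
        **{col: bool(_parse_bool(row.get(col, ""))) for col in _BOOL_COLUMNS},
    )

    record = ProductRecord(
        product_id=(row.get("product_id") or "").strip(),
        brand=(row.get("brand") or "").strip(),
        name=(row.get("name") or "").strip(),
        category=category,
        subcategory_flags=flags,
        lower_age_months=age,
        ingredients=_parse_ingredients(row.get("ingredients", "")),
        label=label,
        **nutrients,
    )
    return record, warnings


def read_products(
    path: str | Path,
    dialect: str = "canonical_csv",
    mapping: Optional[dict[str, str]] = None,
) -> tuple[list[ProductRecord], pd.DataFrame]:
    """Read a product table.

    Parameters
    ----------
    path : file path to a CSV table with a header row.
    dialect : ``canonical_csv`` (schema above) or ``nppm_template``
        (column names remapped via `mapping`, defaulting to the mapping
        file shipped with the package).
    mapping : template-column -> canonical-column renames, used only for
        the ``nppm_template`` dialect.

    Returns
    -------
    (records, errors) : validated records plus an error ledger with one
        row per rejected input row (``severity == "error"``) or kept-with
        -warning row (``severity == "warning"``). No row is silently
        dropped: ``len(records) + (errors.severity == "error").sum()``
        equals the number of input rows.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if dialect == "nppm_template":
        if mapping is None:
            mapping = default_template_mapping()
        frame = frame.rename(columns=mapping)
    elif dialect != "canonical_csv":
        raise ValueError(f"unknown dialect: {dialect!r}")

    records: list[ProductRecord] = []
    ledger_rows: list[dict] = []
    for i, row in enumerate(frame.to_dict(orient="records")):
        try:
            record, warnings = _row_to_record(row)
        except (ValueError, TypeError) as exc:
            ledger_rows.append({
                "row": i + 2,  # 1-based file line including header
                "product_id": (row.get("product_id") or "").strip(),
                "severity": "error",
                "reason": str(exc),
            })
            continue
        records.append(record)
        for msg in warnings:
            ledger_rows.append({
                "row": i + 2,
                "product_id": record.product_id,
                "severity": "warning",
                "reason": msg,
            })
    errors = pd.DataFrame(
        ledger_rows, columns=["row", "product_id", "severity", "reason"]
    )
    return records, errors


def default_template_mapping() -> dict[str, str]:
    import json
    from importlib import resources

    with resources.files("nppm.data").joinpath("template_mapping.json").open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# CSV writing (round-trip partner of read_products)
# ---------------------------------------------------------------------------

def _fmt_float(x: Optional[float]) -> str:
    if x is None:
        return ""
    return repr(float(x))


def _fmt_bool(x: Optional[bool]) -> str:
    if x is None:
        return ""
    return "true" if x else "false"


def records_to_frame(records: Iterable[ProductRecord]) -> pd.DataFrame:
    """Serialize records into the canonical CSV schema (lossless)."""
    rows = []
    for r in records:
        rows.append({
            "product_id": r.product_id,
            "brand": r.brand,
            "name": r.name,
            "category": r.category.value,
            "subcategory_flags": ";".join(sorted(r.subcategory_flags)),
            "age_label": "" if r.lower_age_months is None
                         else f"{r.lower_age_months} months",
            "energy_kcal_100g": _fmt_float(r.energy_kcal_100g),
            "prepared_energy_kcal_100g": _fmt_float(r.prepared_energy_kcal_100g),
            "protein_g_100g": _fmt_float(r.protein_g_100g),
            "fat_g_100g": _fmt_float(r.fat_g_100g),
            "total_sugar_g_100g": _fmt_float(r.total_sugar_g_100g),
            "salt_g_100g": _fmt_float(r.salt_g_100g),
            "sodium_mg_100g": "",
            "serving_g": _fmt_float(r.serving_g),
            "ingredients": "|".join(
                name if pct is None else f"{name}:{pct!r}"
                for name, pct in r.ingredients
            ),
            "claim_texts": "|".join(r.label.claim_texts),
            **{col: _fmt_bool(getattr(r.label, col)) for col in _BOOL_COLUMNS},
            "name_reflects_main_ingredients":
                _fmt_bool(r.label.name_reflects_main_ingredients),
        })
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


def write_products(records: Sequence[ProductRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
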