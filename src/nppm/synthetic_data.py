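"""Synthetic product tables with planted, exactly-known ground truth.

The generator emulates the structure of a market survey of foods for
infants and young children: an eight-category product mix, category-
conditional nutrient distributions (truncated normals bounded at
physical limits), ingredient lists with controllable prevalence of
prohibited sugar sources, and label fields with controllable
prevalences of claims, breastfeeding statements, spouts and so on.

Planting is *outcome-first*: for every product the generator first
fixes the pass/fail verdict of each criterion (exact counts, not
Bernoulli draws), then samples a nutrient value from the pass or fail
side of the governing threshold. The emitted truth ledger is therefore
exact by construction, and an independent rule engine run over the
generated table must reproduce it cell for cell.

Planted quantities that are exact by count: the category mix, the age
band mix, the per-category overall nutrient verdict, the prohibited
(added/free) sugar prevalence, and every label-field prevalence.
Per-criterion fail counts are targeted exactly too, but may be
perturbed by at most the coverage step that guarantees every
overall-failing product fails at least one criterion.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingestion import (AgeBucket, Category, LabelInfo, ProductRecord)
from .nutrient_rules import RuleTable
from .summary_stats import round_half_up

CATEGORY_ORDER = ("Cereals", "Dairy", "FruitVeg", "Meals", "Snacks",
                  "Ingredients", "Confectionery", "Drinks")

# Ingredient pools. Safe terms must not contain any prohibited lexicon
# pattern as a substring; prohibited terms all match the added/free
# classes of the default sugar lexicon.
SAFE_INGREDIENTS = (
    "carrots", "sweet potato", "peas", "broccoli", "apple", "banana",
    "pear", "mango", "oats", "rice", "wheat flour", "whole milk",
    "chicken", "beef", "salmon", "cod", "tomatoes", "spinach",
    "lentils", "quinoa", "parsnips", "pumpkin", "butternut squash",
    "courgette", "potatoes", "onion",
)
PROHIBITED_INGREDIENTS = (
    "sugar", "cane sugar", "glucose syrup", "honey",
    "apple juice concentrate", "grape juice", "golden syrup",
    "fructose", "agave syrup", "brown sugar", "dextrose",
)
#: Food words used to construct names that fail the clarity heuristic;
#: none of them occur in the safe pool.
NAME_DISTRACTORS = ("strawberry", "cherry", "pineapple", "plum",
                    "vanilla", "melon")
NAME_FORMS = ("Purée", "Porridge", "Meal", "Bites", "Pouch", "Bake", "Mash")

CLAIM_POOL = (
    "no added sugar", "organic", "1 of your 5 a day",
    "supports healthy growth", "yummy", "source of vitamins",
    "delicious", "no added salt", "perfect for little hands",
)

_AGE_MONTHS = {"under6": 4, "m6to9": 6, "m10to11": 10, "m12plus": 12}

NUTRIENT_PLANT_ORDER = ("energy", "sugar_pct", "salt", "protein", "fat")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_category_mix() -> dict[str, float]:
    # survey mix: meals 38 %, fruit & veg 30 %, snacks 16 %, cereals 11 %,
    # confectionery 3 %, dairy/ingredients/drinks small
    n = 469.0
    return {"Cereals": 53 / n, "Dairy": 6 / n, "FruitVeg": 139 / n,
            "Meals": 178 / n, "Snacks": 76 / n, "Ingredients": 1 / n,
            "Confectionery": 15 / n, "Drinks": 1 / n}


def _default_age_mix() -> dict[str, float]:
    n = 469.0
    return {"under6": 66 / n, "m6to9": 256 / n, "m10to11": 58 / n,
            "m12plus": 89 / n}


def _default_overall_fail() -> dict[str, float]:
    return {"Cereals": 17 / 53, "Dairy": 2 / 6, "FruitVeg": 0.46,
            "Meals": 0.64, "Snacks": 0.67, "Ingredients": 0.0}


def _default_criterion_fail() -> dict[str, dict[str, float]]:
    return {
        "Cereals": {"energy": 0.02, "protein": 0.05, "fat": 0.02,
                    "salt": 0.10},
        "Dairy": {"energy": 1 / 6},
        "FruitVeg": {"energy": 0.40},
        "Meals": {"energy": 0.22, "protein": 0.10, "fat": 0.01,
                  "sugar_pct": 0.48, "salt": 0.225},
        "Snacks": {"energy": 0.51, "fat": 0.05, "sugar_pct": 0.33,
                   "salt": 0.10},
        "Ingredients": {},
    }


def _default_added_sugar_fail() -> dict[str, float]:
    return {"Cereals": 0.19, "Dairy": 1 / 6, "FruitVeg": 0.19,
            "Meals": 0.19, "Snacks": 0.19, "Ingredients": 0.0}


def _default_fop_required() -> dict[str, float]:
    return {"FruitVeg": 0.80, "Cereals": 0.25, "Dairy": 1 / 3}


def _default_flag_prevalence() -> dict[str, dict[str, float]]:
    return {
        "Cereals": {"is_dry_cereal": 1.0, "contains_milk": 0.6},
        "Meals": {"is_savoury_meal": 1.0,
                  "contains_meat_poultry_fish": 0.4,
                  "contains_cheese": 0.15},
        "Snacks": {"is_fruit_based_snack": 0.5},
    }


def _default_label_rates() -> dict:
    return {
        "claimed": 1.0,                 # products carrying >=1 claim
        "breastfeeding_pass": 0.05,     # adequate statement present
        "statement_inadequate": 0.10,   # statement present but inadequate
        "name_clarity_pass": 0.71,
        "preparation_pass": 0.63,       # among categories needing prep
        "ingredient_list_fail": {"Cereals": 0.42, "default": 0.25},
        "spout": {"FruitVeg": (0.60, 0.16), "Meals": (0.20, 0.86)},
        "fop_flag_present": 0.0,        # among products requiring the flag
        "proportion_declared_pct": (30.0, 80.0),
    }


def _default_distributions() -> dict[str, dict[str, tuple]]:
    # (mean, sd, lower bound, upper bound); quantities named *_100kcal
    # are sampled on the per-100 kcal basis, pctE as percent of energy,
    # everything else per 100 g of product as sold.
    return {
        "Cereals": {
            "energy": (391, 24, 250, 480),
            "energy_prepared": (95, 14, 60, 160),
            "protein_100kcal": (3.2, 1.2, 0.3, 9.0),
            "fat_100kcal": (1.4, 1.0, 0.0, 8.0),
            "salt_100kcal": (0.055, 0.035, 0.0, 0.30),
            "pctE": (17, 7, 1, 60),
        },
        "Dairy": {
            "energy": (74, 9, 40, 110),
            "protein_g": (2.6, 0.4, 1.0, 5.0),
            "fat_100kcal": (3.1, 0.8, 0.5, 8.0),
            "salt_100kcal": (0.095, 0.02, 0.01, 0.30),
            "pctE": (24, 8, 2, 60),
        },
        "FruitVeg": {
            "energy": (64, 18, 20, 130),
            "protein_g": (1.3, 0.8, 0.0, 5.0),
            "fat_100kcal": (1.7, 0.9, 0.0, 8.0),
            "salt_100kcal": (0.05, 0.025, 0.0, 0.30),
            "pctE": (55, 15, 2, 90),
        },
        "Meals": {
            "energy": (69, 13, 25, 150),
            "protein_100kcal": (4.6, 1.2, 0.3, 9.0),
            "fat_100kcal": (3.2, 1.0, 0.2, 10.0),
            "salt_100kcal": (0.115, 0.03, 0.0, 0.45),
            "pctE": (14.5, 4.0, 0.5, 60),
        },
        "Snacks": {
            "energy": (416, 61, 250, 620),
            "serving_kcal": (46, 10, 10, 120),
            "protein_g": (7.5, 1.8, 2.0, 15.0),
            "fat_100kcal": (2.9, 0.9, 0.2, 8.0),
            "salt_100kcal": (0.045, 0.025, 0.0, 0.30),
            "pctE": (12, 6, 0.5, 60),
        },
        "Ingredients": {
            "energy": (350, 60, 100, 500),
            "protein_g": (2.0, 1.0, 0.0, 10.0),
            "fat_100kcal": (1.0, 0.8, 0.0, 8.0),
            "salt_100kcal": (0.04, 0.02, 0.0, 0.30),
            "pctE": (10, 5, 0.5, 50),
        },
        "Confectionery": {
            "energy": (380, 60, 200, 600),
            "protein_g": (3.0, 1.5, 0.0, 10.0),
            "fat_g": (12.0, 6.0, 0.0, 40.0),
            "sugar_g": (45.0, 10.0, 5.0, 90.0),
            "salt_g": (0.10, 0.06, 0.0, 1.0),
        },
        "Drinks": {
            "energy": (45, 10, 15, 90),
            "protein_g": (0.5, 0.3, 0.0, 3.0),
            "fat_g": (0.4, 0.3, 0.0, 3.0),
            "sugar_g": (9.0, 2.0, 1.0, 20.0),
            "salt_g": (0.04, 0.03, 0.0, 0.5),
        },
    }


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the generator.

    Defaults are calibrated to the surveyed market: 469 products with
    the 38/30/16 % meals/fruit-veg/snacks mix, category nutrient means
    near the survey's summary table, 19 % prohibited-sugar prevalence,
    5 % adequate breastfeeding statements and a 67 % overall snack
    fail rate.
    """

    n: int = 469
    seed: int = 20230201
    category_mix: dict[str, float] = field(default_factory=_default_category_mix)
    age_mix: dict[str, float] = field(default_factory=_default_age_mix)
    overall_fail: dict[str, float] = field(default_factory=_default_overall_fail)
    criterion_fail: dict[str, dict[str, float]] = field(
        default_factory=_default_criterion_fail)
    added_sugar_fail: dict[str, float] = field(
        default_factory=_default_added_sugar_fail)
    fop_required: dict[str, float] = field(default_factory=_default_fop_required)
    flag_prevalence: dict[str, dict[str, float]] = field(
        default_factory=_default_flag_prevalence)
    label_rates: dict = field(default_factory=_default_label_rates)
    distributions: dict[str, dict[str, tuple]] = field(
        default_factory=_default_distributions)

    def copy(self) -> "SyntheticConfig":
        return copy.deepcopy(self)


def default_config() -> SyntheticConfig:
    return SyntheticConfig()


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if not lo < hi:
        raise ValueError(f"empty truncation interval [{lo}, {hi}]")
    if sd <= 0:
        raise ValueError("sd must be positive")
    for _ in range(200):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.ppf(rng.uniform(1e-9, 1 - 1e-9), a, b,
                                     loc=mean, scale=sd))


def _margin(threshold: float) -> float:
    return max(1e-9, 1e-6 * abs(threshold))


def _sample_sided(rng, spec, threshold: float, direction: str,
                  want_pass: bool, strict_exceed: bool = False) -> float:
    """Sample from `spec` on the pass or fail side of a threshold.

    A small margin keeps samples away from the boundary so that values
    survive per-100 g round trips without flipping verdicts. With
    `strict_exceed` the "pass" side means strictly above (used for the
    FOP trigger, where "exceeding" is strict).
    """
    mean, sd, lo, hi = spec
    m = _margin(threshold)
    above = (direction == "ge") == want_pass
    if strict_exceed:
        above = want_pass
    if above:
        lo = max(lo, threshold + m)
    else:
        hi = min(hi, threshold - m)
    if not lo < hi:
        raise ValueError(
            f"infeasible config: bounds [{spec[2]}, {spec[3]}] leave no "
            f"room on the {'pass' if want_pass else 'fail'} side of "
            f"threshold {threshold}")
    return _truncated_normal(rng, mean, sd, lo, hi)


def _exact_mask(rng: np.random.Generator, n: int, count: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    mask[:count] = True
    rng.shuffle(mask)
    return mask


def _largest_remainder(props: dict[str, float], n: int,
                       order: Sequence[str]) -> dict[str, int]:
    keys = [k for k in order if props.get(k, 0) > 0]
    raw = np.array([props[k] * n for k in keys])
    counts = np.floor(raw).astype(int)
    short = n - counts.sum()
    for i in np.argsort(-(raw - counts))[:short]:
        counts[i] += 1
    return dict(zip(keys, counts.tolist()))


# ---------------------------------------------------------------------------
# Config validation
# ---------------------------------------------------------------------------

def _validate_config(config: SyntheticConfig, rules: RuleTable) -> None:
    total = sum(config.category_mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"category mix sums to {total}, expected 1")
    if abs(sum(config.age_mix.values()) - 1.0) > 1e-6:
        raise ValueError("age mix must sum to 1")
    for name, rates in (("overall_fail", config.overall_fail),
                        ("added_sugar_fail", config.added_sugar_fail),
                        ("fop_required", config.fop_required)):
        for cat, rate in rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name}[{cat}] = {rate} outside [0, 1]")
    for cat, crit in config.criterion_fail.items():
        for criterion, rate in crit.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(
                    f"criterion_fail[{cat}][{criterion}] = {rate} outside [0, 1]")
    for cat, rate in config.added_sugar_fail.items():
        if rate - config.overall_fail.get(cat, 0.0) > 1e-9:
            raise ValueError(
                f"infeasible config: added-sugar fail rate {rate} in {cat} "
                f"exceeds the overall fail rate")
    _check_bounds_straddle(config, rules)


def _dist_key(cat: str, criterion: str) -> str:
    if criterion == "energy":
        if cat == "Cereals":
            return "energy_prepared"
        if cat == "Snacks":
            return "serving_kcal"
        return "energy"
    if criterion == "sugar_pct":
        return "pctE"
    if criterion == "protein":
        return "protein_100kcal"
    return f"{criterion}_100kcal"


def _check_bounds_straddle(config: SyntheticConfig, rules: RuleTable) -> None:
    """Every planted verdict side must have room inside the truncation
    bounds of its sampling distribution (error before sampling)."""
    for cat, rates in config.criterion_fail.items():
        if cat in rules.non_marketable:
            continue
        dist = config.distributions.get(cat, {})
        for criterion in NUTRIENT_PLANT_ORDER:
            rate = rates.get(criterion, 0.0)
            spec = dist.get(_dist_key(cat, criterion))
            if spec is None:
                continue
            _, _, lo, hi = spec
            for entry in rules.entries:
                if (entry.criterion != criterion or not entry.applicable
                        or entry.threshold is None
                        or cat not in entry.categories):
                    continue
                t, d = entry.threshold, entry.direction
                fail_ok = lo < t if d == "ge" else t < hi
                pass_ok = t < hi if d == "ge" else lo < t
                if rate > 0 and not fail_ok:
                    raise ValueError(
                        f"infeasible config: {cat} {criterion} bounds "
                        f"[{lo}, {hi}] leave no room on the fail side of "
                        f"threshold {t}")
                if rate < 1 and not pass_ok:
                    raise ValueError(
                        f"infeasible config: {cat} {criterion} bounds "
                        f"[{lo}, {hi}] leave no room on the pass side of "
                        f"threshold {t}")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _stub(cat: str, flags: frozenset[str]) -> ProductRecord:
    return ProductRecord(product_id="stub", category=Category(cat),
                         subcategory_flags=flags)


def _criterion_threshold(rules: RuleTable, criterion: str,
                         stub: ProductRecord) -> Optional[tuple[float, str]]:
    entry = rules.lookup(criterion, stub)
    if entry is None or not entry.applicable or entry.threshold is None:
        return None
    return entry.threshold, entry.direction


def generate_products(
    config: Optional[SyntheticConfig] = None,
    seed: Optional[int] = None,
    rules: Optional[RuleTable] = None,
) -> tuple[list[ProductRecord], pd.DataFrame]:
    """Generate `config.n` products plus the exact ground-truth ledger.

    The ledger has one row per product with the planted verdict of
    every criterion (``pd.NA`` where not applicable), the overall
    verdicts, and the FOP-flag requirement; identical seeds yield
    identical output.
    """
    config = config or default_config()
    rules = rules or RuleTable.default()
    _validate_config(config, rules)
    rng = np.random.default_rng(config.seed if seed is None else seed)

    counts = _largest_remainder(config.category_mix, config.n, CATEGORY_ORDER)
    categories: list[str] = []
    for cat in CATEGORY_ORDER:
        categories.extend([cat] * counts.get(cat, 0))
    n = len(categories)

    # -- global label plantings (exact counts) ---------------------------
    lr = config.label_rates
    age_counts = _largest_remainder(config.age_mix, n,
                                    ("under6", "m6to9", "m10to11", "m12plus"))
    age_pool: list[str] = []
    for bucket, cnt in age_counts.items():
        age_pool.extend([bucket] * cnt)
    age_assign = np.array(age_pool, dtype=object)
    rng.shuffle(age_assign)

    bf_pass = _exact_mask(rng, n, round_half_up(n * lr["breastfeeding_pass"]))
    claimed = _exact_mask(rng, n, round_half_up(n * lr["claimed"]))
    name_pass = _exact_mask(rng, n, round_half_up(n * lr["name_clarity_pass"]))

    prep_cats = ("Cereals", "Meals", "Ingredients")
    prep_applicable = np.array([c in prep_cats for c in categories])
    n_prep = int(prep_applicable.sum())
    prep_pass_sub = _exact_mask(rng, n_prep,
                                round_half_up(n_prep * lr["preparation_pass"]))
    prep_pass = np.zeros(n, dtype=bool)
    prep_pass[prep_applicable] = prep_pass_sub

    ing_fail_rates = lr["ingredient_list_fail"]
    ing_fail = np.zeros(n, dtype=bool)
    spout = np.zeros(n, dtype=bool)
    spout_warn = np.zeros(n, dtype=bool)
    cat_arr = np.array(categories, dtype=object)
    for cat in CATEGORY_ORDER:
        idx = np.flatnonzero(cat_arr == cat)
        if idx.size == 0:
            continue
        rate = ing_fail_rates.get(cat, ing_fail_rates.get("default", 0.0))
        ing_fail[idx] = _exact_mask(rng, idx.size,
                                    round_half_up(idx.size * rate))
        if cat in lr["spout"]:
            p_spout, p_warn = lr["spout"][cat]
            s_mask = _exact_mask(rng, idx.size,
                                 round_half_up(idx.size * p_spout))
            spout[idx] = s_mask
            s_idx = idx[s_mask]
            spout_warn[s_idx] = _exact_mask(
                rng, s_idx.size, round_half_up(s_idx.size * p_warn))

    # -- per-category nutrient planting ----------------------------------
    verdicts: dict[str, np.ndarray] = {
        crit: np.full(n, None, dtype=object)
        for crit in ("energy", "protein", "fat", "sugar_pct", "salt",
                     "added_sugar")
    }
    overall_fail_mask = np.zeros(n, dtype=bool)
    fop_req = np.zeros(n, dtype=bool)
    flags_per_product: list[frozenset[str]] = [frozenset()] * n

    for cat in CATEGORY_ORDER:
        idx = np.flatnonzero(cat_arr == cat)
        n_c = idx.size
        if n_c == 0:
            continue
        marketable = cat not in rules.non_marketable
        # subcategory flags
        prevalences = config.flag_prevalence.get(cat, {})
        flag_draws = {f: rng.random(n_c) < p for f, p in prevalences.items()}
        cat_flags = [
            frozenset(f for f, mask in flag_draws.items() if mask[j])
            for j in range(n_c)
        ]
        for j, i in enumerate(idx):
            flags_per_product[i] = cat_flags[j]
        if not marketable:
            overall_fail_mask[idx] = True
            continue

        # applicability per product, from the rule table itself
        applicable: dict[str, np.ndarray] = {}
        thresholds: dict[str, list] = {}
        for crit in NUTRIENT_PLANT_ORDER:
            app = np.zeros(n_c, dtype=bool)
            th: list = [None] * n_c
            for j in range(n_c):
                t = _criterion_threshold(rules, crit, _stub(cat, cat_flags[j]))
                if t is not None:
                    app[j] = True
                    th[j] = t
            applicable[crit] = app
            thresholds[crit] = th

        f_total = round_half_up(n_c * config.overall_fail.get(cat, 0.0))
        fail_mask = _exact_mask(rng, n_c, f_total)
        fail_idx = np.flatnonzero(fail_mask)
        overall_fail_mask[idx[fail_idx]] = True

        a_c = round_half_up(n_c * config.added_sugar_fail.get(cat, 0.0))
        if a_c > fail_idx.size:
            raise ValueError(
                f"infeasible config: {a_c} added-sugar failures requested in "
                f"{cat} but only {fail_idx.size} overall failures")
        added_fail = set(rng.choice(fail_idx, size=a_c, replace=False).tolist()
                         ) if a_c else set()
        covered = set(added_fail)
        crit_fail: dict[str, set] = {"added_sugar": added_fail}
        rates = config.criterion_fail.get(cat, {})
        for crit in NUTRIENT_PLANT_ORDER:
            app = applicable[crit]
            if not app.any():
                crit_fail[crit] = set()
                continue
            target = round_half_up(int(app.sum()) * rates.get(crit, 0.0))
            candidates = [int(j) for j in fail_idx if app[j]]
            target = min(target, len(candidates))
            uncov = [j for j in candidates if j not in covered]
            cov = [j for j in candidates if j in covered]
            rng.shuffle(uncov)
            rng.shuffle(cov)
            take = set(uncov[:target])
            if len(take) < target:
                take |= set(cov[:target - len(take)])
            crit_fail[crit] = take
            covered |= take
        # force-cover: every failing product fails at least one criterion
        for j in fail_idx:
            if int(j) in covered:
                continue
            for crit in NUTRIENT_PLANT_ORDER:
                if applicable[crit][j]:
                    crit_fail[crit].add(int(j))
                    covered.add(int(j))
                    break
            else:
                raise ValueError(
                    f"infeasible config: product in {cat} has no applicable "
                    "criterion to carry its planted failure")

        for crit in NUTRIENT_PLANT_ORDER:
            col = verdicts["sugar_pct" if crit == "sugar_pct" else crit]
            for j in range(n_c):
                if applicable[crit][j]:
                    col[idx[j]] = j not in crit_fail[crit]
        for j in range(n_c):
            verdicts["added_sugar"][idx[j]] = j not in added_fail

        # FOP requirement (independent of the composition verdicts)
        if cat in config.fop_required and cat in rules.fop_thresholds:
            k = round_half_up(n_c * config.fop_required[cat])
            fop_req[idx[_exact_mask(rng, n_c, k)]] = True

    # -- value sampling and record assembly ------------------------------
    records: list[ProductRecord] = []
    ledger_rows: list[dict] = []
    lexicon_pool = list(SAFE_INGREDIENTS)
    prop_lo, prop_hi = lr["proportion_declared_pct"]

    for i in range(n):
        cat = categories[i]
        flags = flags_per_product[i]
        dist = config.distributions[cat]
        marketable = cat not in rules.non_marketable
        stub = _stub(cat, flags)

        nutrients = _sample_nutrients(
            rng, cat, flags, dist, rules, stub,
            {crit: verdicts[crit][i] for crit in verdicts},
            bool(fop_req[i]))

        # ingredients
        k = int(rng.integers(3, 6))
        chosen = list(rng.choice(lexicon_pool, size=k, replace=False))
        if "contains_meat_poultry_fish" in flags and not any(
                c in ("chicken", "beef", "salmon", "cod") for c in chosen):
            chosen.append(str(rng.choice(["chicken", "beef", "salmon", "cod"])))
        if "contains_cheese" in flags and "cheddar cheese" not in chosen:
            chosen.append("cheddar cheese")
        if "contains_milk" in flags and "whole milk" not in chosen:
            chosen.append("whole milk")
        added_verdict = verdicts["added_sugar"][i]
        has_prohibited = added_verdict is False or (
            not marketable and rng.random() < 0.5)
        if has_prohibited:
            term = str(rng.choice(PROHIBITED_INGREDIENTS))
            chosen.insert(int(rng.integers(1, 3)), term)
        declared = not ing_fail[i]
        ingredients = [
            (name, round(float(rng.uniform(prop_lo, prop_hi)), 1)
             if declared and pos == 0 else None)
            for pos, name in enumerate(chosen)
        ]

        # name
        form = str(rng.choice(NAME_FORMS))
        lead = chosen[0].title()
        if name_pass[i]:
            name = f"{lead} {form}"
        else:
            ing_tokens = {tok for nm, _ in ingredients
                          for tok in nm.lower().split()}
            options = [d for d in NAME_DISTRACTORS if d not in ing_tokens]
            name = f"{str(rng.choice(options)).title()} & {lead} {form}"

        # age
        bucket = str(age_assign[i])
        months = _AGE_MONTHS[bucket]
        fmt = int(rng.integers(0, 3))
        if fmt == 0:
            age_label_months = months
            age_text = f"from {months} months"
        elif fmt == 1:
            age_text = f"{months} months+"
        else:
            age_text = f"{months}–{months + 6} months"

        claim_texts = (
            [str(c) for c in rng.choice(CLAIM_POOL,
                                        size=int(rng.integers(1, 4)),
                                        replace=False)]
            if claimed[i] else [])

        label = LabelInfo(
            claim_texts=claim_texts,
            has_breastfeeding_statement=bool(
                bf_pass[i] or rng.random() < lr["statement_inadequate"]),
            breastfeeding_statement_adequate=bool(bf_pass[i]),
            has_preparation_instructions=bool(
                prep_pass[i] if prep_applicable[i] else rng.random() < 0.5),
            has_spout=bool(spout[i]),
            has_spout_warning=bool(spout_warn[i]),
            has_fop_sugar_flag=bool(
                fop_req[i] and rng.random() < lr["fop_flag_present"]),
            name_reflects_main_ingredients=None,
            ingredient_proportions_declared=declared,
        )

        extra_flags = set(flags)
        if label.has_spout and cat == "FruitVeg":
            extra_flags.add("is_puree_with_spout")

        record = ProductRecord(
            product_id=f"P{i:05d}",
            brand=f"Brand{int(rng.integers(1, 22)):02d}",
            name=name,
            category=Category(cat),
            subcategory_flags=frozenset(extra_flags),
            lower_age_months=months,
            ingredients=ingredients,
            label=label,
            serving_g=nutrients.pop("serving_g", None),
            prepared_energy_kcal_100g=nutrients.pop("prepared", None),
            energy_kcal_100g=nutrients["energy"],
            protein_g_100g=nutrients["protein"],
            fat_g_100g=nutrients["fat"],
            total_sugar_g_100g=nutrients["sugar"],
            salt_g_100g=nutrients["salt"],
        )
        records.append(record)

        # ledger row
        promo = _promotion_truth(
            cat, months, claim_texts, bf_pass[i], label, name_pass[i],
            declared, prep_applicable[i], prep_pass[i], fop_req[i])
        nutrient_cols = {
            crit: (pd.NA if verdicts[crit][i] is None
                   else bool(verdicts[crit][i]))
            for crit in verdicts
        }
        ledger_rows.append({
            "product_id": record.product_id,
            "category": cat,
            "age_bucket": bucket,
            "marketable": marketable,
            "marketability": marketable,
            **nutrient_cols,
            "fruit_content": pd.NA,
            "added_water": pd.NA,
            "fop_required": bool(fop_req[i]),
            "nutrient_compliant": not overall_fail_mask[i],
            **promo,
        })

    ledger = pd.DataFrame(ledger_rows)
    return records, ledger


def _promotion_truth(cat, months, claim_texts, bf_ok, label, name_ok,
                     declared, prep_app, prep_ok, fop_required) -> dict:
    claims_ok = not claim_texts
    age_ok = months >= 6
    spout_ok = pd.NA if not label.has_spout else bool(label.has_spout_warning)
    prep = pd.NA if not prep_app else bool(prep_ok)
    fop_label = pd.NA if not fop_required else bool(label.has_fop_sugar_flag)
    parts = [claims_ok, age_ok, bool(bf_ok), bool(name_ok), bool(declared)]
    for extra in (spout_ok, prep, fop_label):
        if extra is not pd.NA:
            parts.append(bool(extra))
    return {
        "claims": claims_ok,
        "age_label": age_ok,
        "breastfeeding": bool(bf_ok),
        "spout_warning": spout_ok,
        "name_clarity": bool(name_ok),
        "ingredient_list": bool(declared),
        "preparation_instructions": prep,
        "fop_label": fop_label,
        "promotion_compliant": all(parts),
    }


def _sample_nutrients(rng, cat, flags, dist, rules, stub, verdict,
                      fop_required: bool) -> dict:
    """Sample the nutrient panel consistent with the planted verdicts."""
    out: dict = {}
    kcal_per_g = rules.kcal_per_g_carbohydrate

    # energy (and prepared energy / serving size)
    if cat == "Cereals":
        energy = _truncated_normal(rng, *dist["energy"])
        t = _criterion_threshold(rules, "energy", stub)
        if verdict["energy"] is None or t is None:
            out["prepared"] = _truncated_normal(rng, *dist["energy_prepared"])
        else:
            out["prepared"] = _sample_sided(
                rng, dist["energy_prepared"], t[0], t[1], verdict["energy"])
    elif cat == "Snacks":
        energy = _truncated_normal(rng, *dist["energy"])
        t = _criterion_threshold(rules, "energy", stub)
        if verdict["energy"] is None or t is None:
            serving_kcal = _truncated_normal(rng, *dist["serving_kcal"])
        else:
            serving_kcal = _sample_sided(
                rng, dist["serving_kcal"], t[0], t[1], verdict["energy"])
        out["serving_g"] = serving_kcal / energy * 100.0
    else:
        t = _criterion_threshold(rules, "energy", stub)
        if verdict["energy"] is None or t is None:
            energy = _truncated_normal(rng, *dist["energy"])
        else:
            energy = _sample_sided(rng, dist["energy"], t[0], t[1],
                                   verdict["energy"])
    out["energy"] = energy
    if "serving_g" not in out and cat not in ("Confectionery", "Drinks"):
        out["serving_g"] = float(rng.uniform(70, 130))

    # sugar: from % energy, driven by the sugar rule or the FOP trigger
    if cat in ("Confectionery", "Drinks"):
        out["sugar"] = _truncated_normal(rng, *dist["sugar_g"])
    else:
        fop_threshold = rules.fop_thresholds.get(cat)
        if verdict["sugar_pct"] is not None:
            t = _criterion_threshold(rules, "sugar_pct", stub)
            pct = _sample_sided(rng, dist["pctE"], t[0], t[1],
                                verdict["sugar_pct"])
        elif fop_threshold is not None:
            pct = _sample_sided(rng, dist["pctE"], fop_threshold, "ge",
                                fop_required, strict_exceed=True)
        else:
            pct = _truncated_normal(rng, *dist["pctE"])
        out["sugar"] = pct * energy / (100.0 * kcal_per_g)

    # protein
    if cat in ("Confectionery", "Drinks"):
        out["protein"] = _truncated_normal(rng, *dist["protein_g"])
    elif "protein_100kcal" in dist:
        t = _criterion_threshold(rules, "protein", stub)
        if verdict["protein"] is None or t is None:
            v = _truncated_normal(rng, *dist["protein_100kcal"])
        else:
            v = _sample_sided(rng, dist["protein_100kcal"], t[0], t[1],
                              verdict["protein"])
        out["protein"] = v * energy / 100.0
    else:
        out["protein"] = _truncated_normal(rng, *dist["protein_g"])

    # fat and salt (per-100 kcal bases)
    for crit, key, gkey in (("fat", "fat_100kcal", "fat_g"),
                            ("salt", "salt_100kcal", "salt_g")):
        if cat in ("Confectionery", "Drinks"):
            out[crit] = _truncated_normal(rng, *dist[gkey])
            continue
        t = _criterion_threshold(rules, crit, stub)
        if verdict[crit] is None or t is None:
            v = _truncated_normal(rng, *dist[key])
        else:
            v = _sample_sided(rng, dist[key], t[0], t[1], verdict[crit])
        out[crit] = v * energy / 100.0
    return out


# ---------------------------------------------------------------------------
# Deterministic fixtures
# ---------------------------------------------------------------------------

def make_boundary_fixtures(
    rules: Optional[RuleTable] = None,
    rel_delta: float = 1e-3,
) -> tuple[list[ProductRecord], pd.DataFrame]:
    """Products exactly at, just below and just above every threshold.

    Returns (records, expected) where `expected` has one row per
    (product, criterion) with the expected verdict, plus rows with
    criterion ``fop_required`` for the front-of-pack trigger. Values
    are placed on the governing basis using an energy density of
    100 kcal/100 g so per-100 kcal numbers are exact.
    """
    rules = rules or RuleTable.default()
    records: list[ProductRecord] = []
    expected_rows: list[dict] = []
    counter = 0

    condition_flags = {
        None: frozenset(),
        "contains_milk": frozenset({"is_dry_cereal", "contains_milk"}),
        "contains_meat_poultry_fish": frozenset(
            {"is_savoury_meal", "contains_meat_poultry_fish"}),
        "is_savoury_meal": frozenset({"is_savoury_meal"}),
        "contains_cheese": frozenset({"contains_cheese"}),
        "not is_fruit_based_snack": frozenset(),
    }

    def add(record: ProductRecord, criterion: str, expect: bool) -> None:
        records.append(record)
        expected_rows.append({"product_id": record.product_id,
                              "criterion": criterion,
                              "expected_pass": expect})

    for entry in rules.entries:
        if entry.threshold is None or not entry.applicable:
            continue
        if entry.basis in ("pct_fruit", "pct_water"):
            continue
        flags = condition_flags.get(entry.condition, frozenset())
        thr = entry.threshold
        for rel, at_or_beyond in ((0.0, True),
                                  (-rel_delta, entry.direction == "le"),
                                  (rel_delta, entry.direction == "ge")):
            value = thr * (1 + rel)
            for cat in entry.categories:
                counter += 1
                fields: dict = {
                    "product_id": f"B{counter:04d}",
                    "category": Category(cat),
                    "subcategory_flags": flags,
                    "energy_kcal_100g": 100.0,
                }
                if entry.basis == "kcal_100g":
                    fields["energy_kcal_100g"] = value
                elif entry.basis == "kcal_100g_prepared":
                    fields["prepared_energy_kcal_100g"] = value
                elif entry.basis == "kcal_per_serving":
                    fields["serving_g"] = value  # at 100 kcal/100 g
                elif entry.basis == "g_100kcal":
                    from .nutrient_rules import NUTRIENT_FIELDS
                    fields[NUTRIENT_FIELDS[entry.criterion]] = value
                elif entry.basis == "pct_energy":
                    fields["total_sugar_g_100g"] = (
                        value / rules.kcal_per_g_carbohydrate)
                add(ProductRecord(**fields), entry.criterion, at_or_beyond)

    # FOP trigger: strictly "exceeding", so the boundary itself does not
    # require the flag.
    for cat, thr in rules.fop_thresholds.items():
        for rel, required in ((0.0, False), (-1e-3, False), (1e-3, True)):
            counter += 1
            pct = thr * (1 + rel)
            record = ProductRecord(
                product_id=f"B{counter:04d}", category=Category(cat),
                energy_kcal_100g=100.0,
                total_sugar_g_100g=pct / rules.kcal_per_g_carbohydrate)
            records.append(record)
            expected_rows.append({"product_id": record.product_id,
                                  "criterion": "fop_required",
                                  "expected_pass": required})

    return records, pd.DataFrame(expected_rows)


def make_threshold_grid(
    rules: Optional[RuleTable] = None,
    span: float = 0.10,
    step: float = 0.01,
) -> list[ProductRecord]:
    """A grid of products spanning every threshold +/- `span` in `step`
    steps, for every applicable category, crossed with benign and
    stressed values of the other nutrients (for oracle-equivalence
    testing of the full conjunction)."""
    rules = rules or RuleTable.default()
    records: list[ProductRecord] = []
    counter = 0

    condition_flags = {
        None: frozenset(),
        "contains_milk": frozenset({"is_dry_cereal", "contains_milk"}),
        "contains_meat_poultry_fish": frozenset(
            {"is_savoury_meal", "contains_meat_poultry_fish"}),
        "is_savoury_meal": frozenset({"is_savoury_meal"}),
        "contains_cheese": frozenset({"contains_cheese"}),
        "not is_fruit_based_snack": frozenset(),
    }
    # benign: passes every default criterion at 100 kcal/100 g;
    # stressed: fails fat and sugar, carries a prohibited ingredient.
    profiles = (
        {"protein_g_100g": 4.2, "fat_g_100g": 2.0, "total_sugar_g_100g": 2.0,
         "salt_g_100g": 0.10,
         "ingredients": [("carrots", None), ("rice", None)]},
        {"protein_g_100g": 2.0, "fat_g_100g": 7.0, "total_sugar_g_100g": 5.0,
         "salt_g_100g": 0.30,
         "ingredients": [("apple juice concentrate", None), ("rice", None)]},
        {"protein_g_100g": None, "fat_g_100g": 2.0, "total_sugar_g_100g": 2.0,
         "salt_g_100g": None, "ingredients": []},
        {"protein_g_100g": 5.6, "fat_g_100g": 4.6, "total_sugar_g_100g": 4.0,
         "salt_g_100g": 0.126, "ingredients": [("banana", None)]},
    )

    steps = np.arange(-span, span + step / 2, step)
    from .nutrient_rules import NUTRIENT_FIELDS
    for entry in rules.entries:
        if entry.threshold is None or not entry.applicable:
            continue
        if entry.basis in ("pct_fruit", "pct_water"):
            continue
        flags = condition_flags.get(entry.condition, frozenset())
        for cat in entry.categories:
            for rel in steps:
                value = entry.threshold * (1 + rel)
                for profile in profiles:
                    counter += 1
                    fields = {
                        "product_id": f"G{counter:05d}",
                        "category": Category(cat),
                        "subcategory_flags": flags,
                        "energy_kcal_100g": 100.0,
                        "serving_g": 40.0,
                        "prepared_energy_kcal_100g":
                            100.0 if cat == "Cereals" else None,
                        **{k: v for k, v in profile.items()},
                    }
                    if entry.basis == "kcal_100g":
                        fields["energy_kcal_100g"] = value
                    elif entry.basis == "kcal_100g_prepared":
                        fields["prepared_energy_kcal_100g"] = value
                    elif entry.basis == "kcal_per_serving":
                        fields["serving_g"] = value
                    elif entry.basis == "g_100kcal":
                        fields[NUTRIENT_FIELDS[entry.criterion]] = value
                    elif entry.basis == "pct_energy":
                        fields["total_sugar_g_100g"] = (
                            value / rules.kcal_per_g_carbohydrate)
                    records.append(ProductRecord(**fields))
    return records
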