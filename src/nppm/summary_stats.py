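"""Aggregation of assessments into study-style summary outputs.

Produces per-category product counts, nutrient means with 95 %
t-based confidence intervals on the per-100 g and per-100 kcal bases,
per-criterion fail rates by category or age band, the any-fail overall
verdict rates, and a one-way ANOVA comparing nutrient content per
100 g across categories. Percentages are rounded half-up to integers
for report parity with printed tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingestion import ProductRecord
from .nutrient_rules import (NUTRIENT_CRITERIA, ProductAssessment, RuleTable,
                             per_100kcal)
from .pipeline import ALL_CRITERIA, verdict_frame

NUTRIENT_COLUMNS = {
    "energy_kcal": "energy_kcal_100g",
    "protein_g": "protein_g_100g",
    "fat_g": "fat_g_100g",
    "sugar_g": "total_sugar_g_100g",
    "salt_g": "salt_g_100g",
}


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero upward."""
    return int(math.floor(x + 0.5))


def mean_ci(
    values: Sequence[float],
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Mean with a t-based confidence interval: mean +/- t * sd/sqrt(n).

    With a single observation the CI is undefined (NaN bounds); an
    empty input is an error.
    """
    arr = np.asarray([v for v in values if v is not None and not np.isnan(v)],
                     dtype=float)
    if arr.size == 0:
        raise ValueError("mean_ci requires at least one value")
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, float("nan"), float("nan")
    sd = float(arr.std(ddof=1))
    se = sd / math.sqrt(arr.size)
    tq = float(stats.t.ppf(0.5 + level / 2.0, arr.size - 1))
    return mean, mean - tq * se, mean + tq * se


@dataclass
class AnovaResult:
    """Classical one-way between/within decomposition."""

    nutrient: str
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    degenerate: bool = False  # zero within-group variance with unequal means


def one_way_anova(
    groups: Sequence[Sequence[float]],
    nutrient: str = "",
    min_group_n: int = 1,
) -> AnovaResult:
    """One-way ANOVA across groups (F from the between/within ratio).

    Groups with fewer than `min_group_n` observations are excluded
    before testing. With zero within-group variance everywhere but
    unequal means the F statistic is infinite and p is reported as 0
    with the `degenerate` flag set.
    """
    cleaned = [np.asarray(g, dtype=float) for g in groups]
    cleaned = [g[~np.isnan(g)] for g in cleaned]
    cleaned = [g for g in cleaned if g.size >= max(1, min_group_n)]
    if len(cleaned) < 2:
        raise ValueError("one_way_anova requires at least two groups")
    n_total = sum(g.size for g in cleaned)
    k = len(cleaned)
    if n_total - k < 1:
        raise ValueError("one_way_anova requires residual degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, p = stats.f_oneway(*cleaned)
    degenerate = not np.isfinite(f_stat)
    if degenerate:
        f_stat, p = float("inf"), 0.0
    return AnovaResult(
        nutrient=nutrient, f_statistic=float(f_stat),
        df_between=k - 1, df_within=n_total - k,
        p_value=float(p), degenerate=degenerate)


# ---------------------------------------------------------------------------
# Nutrient summaries (Table 2 analogue)
# ---------------------------------------------------------------------------

def category_nutrient_summary(
    records: Sequence[ProductRecord],
    rules: Optional[RuleTable] = None,
    basis: str = "per_100g",
    categories: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Mean (95 % CI) per nutrient and category.

    `basis` is ``per_100g`` or ``per_100kcal`` (energy stays kcal/100 g
    on either basis; sugar on the per-100 kcal basis is additionally
    reported as percent of energy by the sugar-profile module).
    Non-marketable categories are excluded by default.
    """
    rules = rules or RuleTable.default()
    if categories is None:
        categories = [c for c in
                      ("Cereals", "Dairy", "FruitVeg", "Meals", "Snacks",
                       "Ingredients")
                      if c not in rules.non_marketable]
    rows = []
    for cat in categories:
        sub = [r for r in records if r.category.value == cat]
        if not sub:
            continue
        row: dict = {"category": cat, "n": len(sub)}
        for label, attr in NUTRIENT_COLUMNS.items():
            values = []
            for r in sub:
                v = getattr(r, attr)
                if basis == "per_100kcal" and label != "energy_kcal":
                    v = per_100kcal(v, r.energy_kcal_100g)
                if v is not None:
                    values.append(v)
            if not values:
                row[f"{label}_mean"] = np.nan
                row[f"{label}_ci_low"] = np.nan
                row[f"{label}_ci_high"] = np.nan
                continue
            mean, lo, hi = mean_ci(values)
            row[f"{label}_mean"] = mean
            row[f"{label}_ci_low"] = lo
            row[f"{label}_ci_high"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def nutrient_anova(
    records: Sequence[ProductRecord],
    rules: Optional[RuleTable] = None,
    min_group_n: int = 2,
    categories: Optional[Sequence[str]] = None,
) -> dict[str, AnovaResult]:
    """One-way ANOVA per nutrient (per 100 g) across categories.

    Small categories (n < `min_group_n`, e.g. a single "Ingredients"
    product) are excluded from the comparison.
    """
    rules = rules or RuleTable.default()
    if categories is None:
        categories = [c for c in
                      ("Cereals", "Dairy", "FruitVeg", "Meals", "Snacks",
                       "Ingredients")
                      if c not in rules.non_marketable]
    out = {}
    for label, attr in NUTRIENT_COLUMNS.items():
        groups = []
        for cat in categories:
            values = [getattr(r, attr) for r in records
                      if r.category.value == cat
                      and getattr(r, attr) is not None]
            if values:
                groups.append(values)
        out[label] = one_way_anova(groups, nutrient=label,
                                   min_group_n=min_group_n)
    return out


# ---------------------------------------------------------------------------
# Compliance tables (Tables 3 and 4 analogue)
# ---------------------------------------------------------------------------

_OVERALL_ROWS = ("nutrient_compliant", "promotion_compliant")


def compliance_table(
    assessments: Sequence[ProductAssessment],
    by: str = "category",
) -> pd.DataFrame:
    """Counts and fail percentages per stratum and criterion.

    `by` is ``category``, ``age_bucket`` or ``criterion`` (no
    stratification; one row per criterion over all products). For each
    criterion the denominator is the number of applicable, assessable
    products in the stratum; the ``overall_nutrient`` and
    ``overall_promotion`` rows use the any-fail verdicts. Percentages
    are rounded half-up to integers.
    """
    frame = verdict_frame(assessments)
    if by == "criterion":
        frame = frame.assign(_stratum="all")
    elif by in ("category", "age_bucket"):
        frame = frame.assign(_stratum=frame[by])
    else:
        raise ValueError(f"unknown stratifier {by!r}")

    rows = []
    for stratum, sub in frame.groupby("_stratum", dropna=False, sort=True):
        if pd.isna(stratum) or len(sub) == 0:
            continue
        for criterion in ALL_CRITERIA:
            col = sub[criterion]
            n_app = int(col.notna().sum())
            if n_app == 0:
                continue
            n_fail = int((~col.dropna()).sum())
            rows.append({
                "stratum": stratum, "criterion": criterion,
                "n": len(sub), "n_applicable": n_app, "n_fail": n_fail,
                "pct_fail": round_half_up(100.0 * n_fail / n_app),
            })
        for verdict, name in (("nutrient_compliant", "overall_nutrient"),
                              ("promotion_compliant", "overall_promotion")):
            col = sub[verdict]
            n_app = int(col.notna().sum())
            if n_app == 0:
                continue
            n_fail = int((~col.dropna()).sum())
            rows.append({
                "stratum": stratum, "criterion": name,
                "n": len(sub), "n_applicable": n_app, "n_fail": n_fail,
                "pct_fail": round_half_up(100.0 * n_fail / n_app),
            })
    return pd.DataFrame(
        rows, columns=["stratum", "criterion", "n", "n_applicable",
                       "n_fail", "pct_fail"])


def category_counts(records: Sequence[ProductRecord]) -> pd.DataFrame:
    """Category and lower-age distribution (Table 1 analogue)."""
    from .ingestion import bucket_age

    cats = pd.Series([r.category.value for r in records])
    ages = pd.Series([
        b.value if (b := bucket_age(r.lower_age_months)) is not None else "missing"
        for r in records
    ])
    n = len(records)
    if n == 0:
        return pd.DataFrame(columns=["dimension", "level", "n", "pct"])
    rows = [
        {"dimension": "category", "level": level, "n": int(count),
         "pct": round_half_up(100.0 * count / n)}
        for level, count in cats.value_counts().sort_index().items()
    ] + [
        {"dimension": "age", "level": level, "n": int(count),
         "pct": round_half_up(100.0 * count / n)}
        for level, count in ages.value_counts().sort_index().items()
    ]
    return pd.DataFrame(rows, columns=["dimension", "level", "n", "pct"])


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def report(
    records: Sequence[ProductRecord],
    assessments: Sequence[ProductAssessment],
    outdir: str | Path,
    rules: Optional[RuleTable] = None,
    figure: bool = False,
) -> dict[str, Path]:
    """Write the summary tables as CSV files (deterministic layout).

    Emits category/age counts, nutrient means with CIs on both bases
    with ANOVA p-values, nutrient-criterion fail rates by category and
    by age band, and promotion fail rates by category. With
    ``figure=True`` (requires matplotlib) a means-with-CI figure is
    also written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rules = rules or RuleTable.default()
    paths: dict[str, Path] = {}

    counts = category_counts(records)
    paths["counts"] = outdir / "table1_counts.csv"
    counts.to_csv(paths["counts"], index=False)

    for basis in ("per_100g", "per_100kcal"):
        summary = category_nutrient_summary(records, rules, basis=basis)
        if basis == "per_100g" and not summary.empty:
            anova = nutrient_anova(records, rules)
            anova_frame = pd.DataFrame([
                {"nutrient": a.nutrient, "F": a.f_statistic,
                 "df_between": a.df_between, "df_within": a.df_within,
                 "p_value": a.p_value}
                for a in anova.values()
            ])
            paths["anova"] = outdir / "table2_anova.csv"
            anova_frame.to_csv(paths["anova"], index=False)
        paths[f"nutrients_{basis}"] = outdir / f"table2_nutrients_{basis}.csv"
        summary.to_csv(paths[f"nutrients_{basis}"], index=False)

    by_cat = compliance_table(assessments, by="category")
    paths["fails_by_category"] = outdir / "table3_fails_by_category.csv"
    by_cat.to_csv(paths["fails_by_category"], index=False)

    by_age = compliance_table(assessments, by="age_bucket")
    paths["fails_by_age"] = outdir / "table3_fails_by_age.csv"
    by_age.to_csv(paths["fails_by_age"], index=False)

    promo = by_cat[by_cat.criterion.isin(
        ("claims", "age_label", "breastfeeding", "spout_warning",
         "name_clarity", "ingredient_list", "preparation_instructions",
         "fop_label", "overall_promotion"))]
    paths["promotion"] = outdir / "table4_promotion.csv"
    promo.to_csv(paths["promotion"], index=False)

    if figure:
        paths["figure"] = _means_figure(records, rules,
                                        outdir / "fig2_means.png")
    return paths


def _means_figure(records, rules, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = category_nutrient_summary(records, rules, basis="per_100g")
    fig, axes = plt.subplots(1, len(NUTRIENT_COLUMNS),
                             figsize=(4 * len(NUTRIENT_COLUMNS), 4))
    for ax, label in zip(np.atleast_1d(axes), NUTRIENT_COLUMNS):
        means = summary[f"{label}_mean"]
        err_low = means - summary[f"{label}_ci_low"]
        err_high = summary[f"{label}_ci_high"] - means
        ax.errorbar(summary["category"], means,
                    yerr=[err_low.fillna(0), err_high.fillna(0)],
                    fmt="o", capsize=4)
        ax.set_title(label.replace("_", " "))
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
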