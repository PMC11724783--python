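# nppm

Compliance assessment of commercial foods for infants and young
children (FIYC, under 36 months) against the WHO Regional Office for
Europe's **Nutrient and Promotion Profile Model (NPPM)**.

Market surveys of baby foods repeatedly find products that are too low
in energy, too high in sugar or salt, carry prohibited added sugars,
and are promoted with claims that undermine public-health advice. The
NPPM pairs *nutrient-composition* criteria with *promotional*
requirements; a product is non-compliant overall if it fails **any
single applicable criterion**. This package implements that audit as a
reproducible pipeline: ingestion and validation of labelled product
tables, a configurable rule engine, sugar-source classification from
ingredient lists, promotional checks, and the aggregation used in
compliance studies (category/age compliance tables, nutrient means
with 95 % CIs per 100 g and per 100 kcal, one-way ANOVA across
categories).

## The model

Products are assigned to eight categories (cereals, dairy, fruit &
vegetables, meals, snacks, ingredients, confectionery, drinks).
Confectionery and drinks must not be marketed as FIYC at all. For the
remaining categories, the default nutrient criteria are, with all
printed thresholds inclusive at the boundary:

| criterion | rule (default rule table) |
|---|---|
| energy | dry cereals ≥ 80 kcal/100 g as prepared; dairy, fruit/veg, meals ≥ 60 kcal/100 g; snacks ≤ 50 kcal per serving |
| protein | dry cereals with milk ≤ 5.5 g/100 kcal; savoury meals ≥ 3 g/100 kcal (≥ 4 g/100 kcal with meat, poultry or fish; configurable) |
| fat | ≤ 4.5 g/100 kcal; ≤ 6 g/100 kcal for meat/poultry/fish meals |
| total sugar | ≤ 15 % of energy for meals and non-fruit snacks (4 kcal/g carbohydrate) |
| added sugar | added and free sugar sources (sucrose, syrups, honey, juices, concentrates, …) are prohibited; lexicon-based ingredient classification |
| salt | ≤ 0.125 g/100 kcal; ≤ 0.25 g/100 kcal with cheese |

The per-100 kcal basis is `g/100 g × 100 / kcal/100 g`; percent of
energy from sugar is `sugar g × 4 / kcal × 100`. A front-of-pack (FOP)
high-sugar flag is required when percent of energy from sugar
*strictly exceeds* 30 % (fruit/vegetable, cereals) or 40 % (dairy).

Promotional requirements: no nutrition/health/marketing claims, a
lower age recommendation of at least 6 months, an adequate statement
supporting breastfeeding, a "do not suck from the spout" warning on
spouted packs, a product name that reflects the main ingredients,
declared ingredient proportions, preparation instructions where
preparation is needed, and the FOP flag where required.

The criterion matrix ships as an editable YAML rule table
(`nppm/data/rules.yaml`); the sugar and claim lexicons are two-column
CSVs, all user-replaceable.

## Worked example

```python
import nppm

# a synthetic 469-product market survey with known ground truth
records, truth = nppm.generate_products(nppm.default_config())
assessments = nppm.assess_products(records)

verdicts = nppm.verdict_frame(assessments)
marketable = verdicts[verdicts.marketable.astype(bool)]
print(len(records), "products;",
      f"{100 * marketable.nutrient_compliant.astype(bool).mean():.1f}%",
      "nutrient-compliant")
print("engine vs ground truth mismatches:",
      len(nppm.compare_with_ledger(assessments, truth)))

table = nppm.compliance_table(assessments, by="category")
print(table[table.criterion == "overall_nutrient"]
      [["stratum", "n_applicable", "n_fail", "pct_fail"]])
```

prints

```
469 products; 45.3% nutrient-compliant
engine vs ground truth mismatches: 0
          stratum  n_applicable  n_fail  pct_fail
13        Cereals            53      17        32
21  Confectionery            15      15       100
34          Dairy             6       2        33
42         Drinks             1       1       100
56       FruitVeg           139      64        46
68    Ingredients             1       0         0
84          Meals           178     114        64
97         Snacks            76      51        67
```

Under half of the synthetic survey meets the composition criteria,
with snacks (67 % fail) and meals (64 % fail) worst — the structure
the generator's defaults plant. Confectionery and drinks fail outright
because those categories must not be marketed as FIYC. The same functions run on real product
tables in the canonical CSV schema (see `nppm/ingestion.py` for the
column list), e.g. a survey exported from the NPPM Excel templates via
the `nppm_template` dialect.

A CLI wraps the same library:

```sh
nppm simulate --n 469 --seed 3 --out products.csv --truth truth.csv
nppm ingest products.csv --errors bad_rows.csv
nppm assess products.csv --out verdicts.csv
nppm summarize products.csv --out tables/
```

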