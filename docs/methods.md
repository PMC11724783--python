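# Methods

## The audit model

The package implements the WHO/Europe Nutrient and Promotion Profile
Model (NPPM) as a deterministic rule audit. Each product record —
identity, one of eight categories, subcategory flags, lower age
recommendation, nutrient declaration per 100 g as sold, serving size,
ordered ingredient list, and label facts — is evaluated against two
families of criteria:

* **composition**: marketability (confectionery and drinks may not be
  marketed as foods for infants and young children at all), energy
  density, protein, fat, total sugar as percent of energy, the
  added/free-sugar prohibition, and salt;
* **promotion**: absence of nutrition/health/marketing claims, a
  ≥ 6-month age label, an adequate breastfeeding-support statement, a
  spout warning on spouted packs, name clarity, declared ingredient
  proportions, preparation instructions, and the front-of-pack (FOP)
  high-sugar flag where required.

A product is non-compliant on either dimension if it fails any single
applicable criterion. Criteria that do not apply to a product's
category (the grey cells of published NPPM tables) are vacuous: they
never enter a denominator and can never change a verdict.

## Rule table

The criterion matrix is data, not code: a YAML file keyed by
(criterion, categories, optional subcategory condition) with
threshold, direction, and basis (kcal/100 g, kcal/100 g as prepared,
kcal per serving, g/100 kcal, % of energy). Condition-specific entries
(e.g. the 0.25 g/100 kcal salt allowance with cheese, the 6 g/100 kcal
fat allowance for meat/poultry/fish meals) take precedence over the
generic entry, earlier entries first. Design choices embedded in the
defaults:

* **Inclusive boundaries.** Criteria are printed as "≤"/"≥", so a
  product at exactly 15 %E sugar, 4.5 g fat/100 kcal, 0.125 g
  salt/100 kcal or 60 kcal/100 g passes. The FOP trigger is the one
  deliberate exception: "exceeding 30 %" is read strictly, so 30.0 %
  does not require the flag and 30.01 % does.
* **Energy conversion.** Percent of energy from sugar uses 4 kcal per
  gram of carbohydrate, the standard Atwater factor.
* **Elevated protein minimum for meat/poultry/fish meals.** The model
  requires "higher levels" without a main-text number; the default is
  4.0 g/100 kcal, shipped as an ordinary rule-table entry so users
  with the full criterion matrix can override it.
* **Dry cereals** are assessed on energy as prepared; when the
  prepared value is missing the engine falls back to the dry label
  value and attaches a warning note rather than dropping the product.
* **Fruit-content and added-water cut-offs** exist in the published
  model but without universally printed values; they ship as disabled
  entries (threshold `null`) to be enabled by editing the YAML.
* **Incomplete nutrient panels.** Missing values are never imputed; a
  criterion without its input is "not assessable". The default policy
  assesses the remaining criteria and flags the product; a strict
  policy (`incomplete_policy: strict`) fails it instead.
* **Sodium.** If only sodium is declared, salt g = sodium mg × 2.5 /
  1000.

## Sugar-source classification

Labels declare total sugar but not its provenance, so provenance is
inferred from the ingredient list with a user-extensible lexicon
mapping term patterns to five classes: added, free, liberated,
milk-intrinsic, plant-intrinsic. Matching is case-insensitive,
accent-stripped, longest-pattern-first (so "apple juice concentrate"
is free sugar while "apple" alone is intrinsic), ties broken by
lexicon order. Added and free classes trigger the prohibition;
liberated sugars (purées) are reported but, by default, do not fail a
product — whether puréed fruit in savoury meals should trigger the
prohibition is genuinely unresolved, so it is a switch
(`prohibit_liberated`). The classification is presence-based only; no
attempt is made to split total sugar grams between classes, since
labels do not support it.

## Statistics

Category summaries report nutrient means with 95 % confidence
intervals, mean ± t(0.975, n−1)·sd/√n. The t interval was chosen over
the normal because it is exact under normality and indistinguishable
at the survey's group sizes; with n = 1 the CI is undefined (NaN), and
zero variance gives a zero-width interval. Differences across
categories use classical one-way ANOVA (between/within decomposition,
p from the F distribution; scipy's implementation behind the module
surface). Groups below a minimum size (default 2 — e.g. a singleton
"ingredients" category) are excluded from the comparison. Degenerate
inputs (zero within-group variance with unequal means) are reported
as F = ∞, p = 0 with an explicit flag. Report percentages are rounded
half-up to integers for parity with printed tables.

## Synthetic data

The generator emulates the structure the analysis assumes: the
453-marketable/16-non-marketable split of a 469-product survey
(meals 38 %, fruit & veg 30 %, snacks 16 %, cereals 11 %, the rest
small), truncated-normal nutrient distributions whose means sit at the
published category means (snacks ≈ 416 kcal/100 g, fruit & veg ≈ 64,
meals ≈ 69; per-100 kcal parameters chosen so per-100 g means land
near the published values), an age mix with 14 % of products marketed
under 6 months, 19 % prohibited-sugar prevalence, a 5 % adequate
breastfeeding-statement rate, and per-category overall fail rates
(snacks 67 %, meals 64 %, fruit & veg 46 %). Where the source
material gives only a category-level statement (e.g. energy fail rates
of 40 % for fruit purées, 22 % for meals, 51 % of snacks over 50 kcal
per serving), those per-category values are used directly and the
aggregate rate is whatever they imply.

Planting is outcome-first: verdicts are drawn before values. Exact
counts (round half-up of n × rate, randomly assigned) are planted for
the category and age mixes, the per-category overall verdict, the
prohibited-sugar prevalence, the FOP requirement, and every label
prevalence. Criterion-level failures are then distributed among the
overall-failing products — exact counts targeted, uncovered failing
products force-covered so that every failing product fails at least
one criterion — and nutrient values are sampled from the pass or fail
side of the governing threshold (truncated normal, with a small
margin so values survive CSV round trips without flipping verdicts).
Infeasible configurations (a prohibited-sugar rate above the overall
fail rate; truncation bounds leaving no room on a required side of a
threshold) raise before sampling. Identical seeds produce identical
bytes.

What the generator does **not** emulate: real brand/marketing copy,
correlation between nutrient values beyond what the shared energy
denominator induces, partially-missing nutrient panels, multilingual
labels, or OCR noise. Passing tests therefore demonstrate that the
engine implements the criteria exactly and that the aggregation
reproduces known rates — not that the lexicons capture every claim or
sugar synonym on real UK packaging.

## Verification strategy and problem sizes

* Boundary fixtures place a product exactly at, just below and just
  above every threshold in the rule table for every applicable
  category (inclusive-boundary contract).
* An independent brute-force evaluator, reading the serialized YAML
  and lexicon directly, re-derives every verdict on a ~2,400-product
  grid spanning each threshold ± 10 % in 1 % steps, crossed with
  benign/stressed/incomplete profiles of the other nutrients.
* A 10,000-product survey at the default rates must match its planted
  ledger cell-for-cell (the generator and engine are independent code
  paths) and reproduce the planted counts exactly.
* Frequentist checks: CI coverage within 95 % ± 1 % and ANOVA type-I
  error within 3 SE of 5 % over 10,000 simulations each (n = 30 and
  3 × 20 respectively); the two-group F equals the squared pooled t to
  1e-10.

These sizes keep the full suite under half a minute on one CPU while
making the binomial noise on every checked rate far smaller than the
tolerances involved.

## Known limitations

* The name-clarity heuristic (every food-noun token of the name must
  appear among the top-3 ingredients, with a packaged food-word
  vocabulary) operationalizes what surveys judge manually; a manual
  adjudication column always wins.
* Breastfeeding-statement *adequacy* is an input boolean — the model
  does not define adequacy textually, so the package does not attempt
  to parse it.
* Criterion applicability for preparation instructions, and the
  promotion criteria generally, follow a default applicability
  configuration; surveys using different grey-cell conventions should
  edit it.
* Micronutrient criteria (iron, vitamins) are outside the model's
  current scope and are not implemented.
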