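# Default WHO NPPM nutrient-composition criterion matrix.
# Thresholds are inclusive at the boundary; direction "ge" means the
# observed value must be >= threshold to pass, "le" means <=.
# Entries with a "condition" (a subcategory flag, optionally negated
# with "not ") take precedence over the condition-free entry for the
# same criterion and category.
kcal_per_g_carbohydrate: 4.0
non_marketable: [Confectionery, Drinks]
incomplete_policy: assess_available
fop_pct_energy_thresholds:
  FruitVeg: 30.0
  Cereals: 30.0
  Dairy: 40.0
criteria:
  - criterion: energy
    categories: [Cereals]
    basis: kcal_100g_prepared
    direction: ge
    threshold: 80.0
    note: dry cereals/starches, energy density as prepared
  - criterion: energy
    categories: [Dairy, FruitVeg, Meals]
    basis: kcal_100g
    direction: ge
    threshold: 60.0
  - criterion: energy
    categories: [Snacks]
    basis: kcal_per_serving
    direction: le
    threshold: 50.0
  - criterion: protein
    categories: [Cereals]
    condition: contains_milk
    basis: g_100kcal
    direction: le
    threshold: 5.5
  - criterion: protein
    categories: [Meals]
    condition: contains_meat_poultry_fish
    basis: g_100kcal
    direction: ge
    threshold: 4.0
    note: >-
      elevated minimum for meals containing meat, poultry or fish;
      supplementary-sourced default, override as needed
  - criterion: protein
    categories: [Meals]
    condition: is_savoury_meal
    basis: g_100kcal
    direction: ge
    threshold: 3.0
  - criterion: fat
    categories: [Meals]
    condition: contains_meat_poultry_fish
    basis: g_100kcal
    direction: le
    threshold: 6.0
    note: meals with traditional protein sources
  - criterion: fat
    categories: [Cereals, Dairy, FruitVeg, Meals, Snacks, Ingredients]
    basis: g_100kcal
    direction: le
    threshold: 4.5
  - criterion: sugar_pct
    categories: [Meals]
    basis: pct_energy
    direction: le
    threshold: 15.0
  - criterion: sugar_pct
    categories: [Snacks]
    condition: not is_fruit_based_snack
    basis: pct_energy
    direction: le
    threshold: 15.0
  - criterion: salt
    categories: [Cereals, Dairy, FruitVeg, Meals, Snacks, Ingredients]
    condition: contains_cheese
    basis: g_100kcal
    direction: le
    threshold: 0.25
  - criterion: salt
    categories: [Cereals, Dairy, FruitVeg, Meals, Snacks, Ingredients]
    basis: g_100kcal
    direction: le
    threshold: 0.125
  # Cut-offs below are not stated in the main criteria text; they ship
  # disabled (threshold null) and can be enabled by editing this file.
  - criterion: fruit_content
    categories: [FruitVeg, Snacks, Meals]
    basis: pct_fruit
    direction: le
    threshold: null
    applicable: false
    note: dried/pureed fruit content limit; unstated cut-off, configurable
  - criterion: added_water
    categories: [FruitVeg]
    basis: pct_water
    direction: le
    threshold: null
    applicable: false
    note: maximum added water for vegetable purees; unstated cut-off, configurable
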