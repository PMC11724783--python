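{
  "Product ID": "product_id",
  "Brand": "brand",
  "Product name": "name",
  "Product category": "category",
  "Sub-category flags": "subcategory_flags",
  "Age recommendation": "age_label",
  "Energy (kcal/100g)": "energy_kcal_100g",
  "Energy as prepared (kcal/100g)": "prepared_energy_kcal_100g",
  "Protein (g/100g)": "protein_g_100g",
  "Fat (g/100g)": "fat_g_100g",
  "Total sugar (g/100g)": "total_sugar_g_100g",
  "Salt (g/100g)": "salt_g_100g",
  "Sodium (mg/100g)": "sodium_mg_100g",
  "Serving size (g)": "serving_g",
  "Ingredients": "ingredients",
  "Claims": "claim_texts",
  "Breastfeeding statement": "has_breastfeeding_statement",
  "Breastfeeding statement adequate": "breastfeeding_statement_adequate",
  "Preparation instructions": "has_preparation_instructions",
  "Spout": "has_spout",
  "Spout warning": "has_spout_warning",
  "FOP sugar flag": "has_fop_sugar_flag",
  "Name reflects main ingredients": "name_reflects_main_ingredients",
  "Ingredient proportions declared": "ingredient_proportions_declared"
}
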