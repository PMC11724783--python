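"""Product-table reading, validation, age parsing and round-tripping."""

import io

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nppm import (AgeBucket, bucket_age, parse_lower_age, read_products,
                  records_to_frame, write_products)

HEADER = ("product_id,brand,name,category,subcategory_flags,age_label,"
          "energy_kcal_100g,prepared_energy_kcal_100g,protein_g_100g,"
          "fat_g_100g,total_sugar_g_100g,salt_g_100g,sodium_mg_100g,"
          "serving_g,ingredients,claim_texts,has_breastfeeding_statement,"
          "breastfeeding_statement_adequate,has_preparation_instructions,"
          "has_spout,has_spout_warning,has_fop_sugar_flag,"
          "name_reflects_main_ingredients,ingredient_proportions_declared")


def _read(rows, **kw):
    text = HEADER + "\n" + "\n".join(rows) + ("\n" if rows else "")
    return read_products(io.StringIO(text), **kw)


# Hand-labelled truth for label strings seen on packs.
AGE_LABELS = [
    ("from 4 months", 4),
    ("4 months", 4),
    ("6 months+", 6),
    ("6m+", 6),
    ("12–24 months", 12),
    ("12-24 months", 12),
    ("6-9 months", 6),
    ("10 to 11 months", 10),
    ("from 7 months", 7),
    ("suitable from 6 months", 6),
    ("stage 1 (from 4 months)", 4),
    ("1-3 years", 12),
    ("1 year+", 12),
    ("2 years", 24),
    ("36 months", 36),
    ("10 mths", 10),
    ("8 mo", 8),
    ("babies", None),
    ("", None),
    ("toddler snack", None),
]


@pytest.mark.parametrize("text,months", AGE_LABELS)
def test_parse_lower_age(text, months):
    assert parse_lower_age(text) == months


@pytest.mark.parametrize("months,bucket", [
    (0, AgeBucket.UNDER6), (4, AgeBucket.UNDER6), (5, AgeBucket.UNDER6),
    (6, AgeBucket.M6TO9), (9, AgeBucket.M6TO9),
    (10, AgeBucket.M10TO11), (11, AgeBucket.M10TO11),
    (12, AgeBucket.M12PLUS), (24, AgeBucket.M12PLUS),
    (None, None),
])
def test_bucket_age(months, bucket):
    assert bucket_age(months) == bucket


@given(st.integers(0, 48), st.integers(0, 48))
def test_bucket_age_total_and_monotone(a, b):
    order = [AgeBucket.UNDER6, AgeBucket.M6TO9, AgeBucket.M10TO11,
             AgeBucket.M12PLUS]
    ba, bb = bucket_age(a), bucket_age(b)
    assert ba in order and bb in order
    if a <= b:
        assert order.index(ba) <= order.index(bb)


def test_header_only_file_yields_nothing():
    records, errors = _read([])
    assert records == [] and len(errors) == 0


def test_valid_meals_row_parsed():
    records, errors = _read([
        'p1,BrandA,Chicken Meal,Meals,is_savoury_meal,from 6 months,'
        '69,,3.1,2.2,2.5,0.08,,100,chicken:30|carrots,,true,true,true,'
        'false,false,false,,true'
    ])
    assert len(errors) == 0 and len(records) == 1
    r = records[0]
    assert r.category.value == "Meals"
    assert r.energy_kcal_100g == 69
    assert r.protein_g_100g == 3.1
    assert r.fat_g_100g == 2.2
    assert r.total_sugar_g_100g == 2.5
    assert r.salt_g_100g == 0.08
    assert r.lower_age_months == 6
    assert r.ingredients == [("chicken", 30.0), ("carrots", None)]


def test_unknown_category_rejected_with_reason():
    records, errors = _read([
        'p1,B,X,Sweets,,6 months,100,,1,1,1,0.1,,,,,,,,,,,,'
    ])
    assert records == []
    assert len(errors) == 1
    assert errors.iloc[0]["severity"] == "error"
    assert "unknown category" in errors.iloc[0]["reason"]


def test_negative_nutrient_rejected():
    records, errors = _read([
        'p1,B,X,Meals,,6 months,100,,-1,1,1,0.1,,,,,,,,,,,,'
    ])
    assert records == [] and len(errors) == 1


def test_unparseable_age_kept_with_warning():
    records, errors = _read([
        'p1,B,X,Meals,,little ones,100,,1,1,1,0.1,,,,,,,,,,,,'
    ])
    assert len(records) == 1
    assert records[0].lower_age_months is None
    assert (errors.severity == "warning").all()


def test_row_accounting_is_complete():
    records, errors = _read([
        'p1,B,X,Meals,,6 months,100,,1,1,1,0.1,,,,,,,,,,,,',
        'p2,B,X,Nope,,6 months,100,,1,1,1,0.1,,,,,,,,,,,,',
        'p3,B,X,Drinks,,6 months,50,,1,1,1,0.1,,,,,,,,,,,,',
    ])
    n_rejected = int((errors.severity == "error").sum())
    assert len(records) + n_rejected == 3


def test_decimal_comma_and_sodium_conversion():
    records, _ = _read([
        'p1,B,X,Meals,,6 months,"69,5",,3,2,2,,100,,,,,,,,,,,'
    ])
    assert records[0].energy_kcal_100g == 69.5
    # salt column empty, sodium 100 mg -> 0.25 g salt
    assert records[0].salt_g_100g == pytest.approx(0.25)


def test_category_aliases_accepted():
    records, errors = _read([
        'p1,B,X,Fruit and vegetables,,6 months,64,,1,1,8,0.03,,,,,,,,,,,,',
        'p2,B,X,Confectionary,,6 months,380,,1,1,40,0.1,,,,,,,,,,,,',
    ])
    assert len(errors) == 0
    assert [r.category.value for r in records] == ["FruitVeg", "Confectionery"]


def test_nppm_template_dialect_maps_columns():
    text = ("Product ID,Product category,Age recommendation,"
            "Energy (kcal/100g),Protein (g/100g),Fat (g/100g),"
            "Total sugar (g/100g),Salt (g/100g)\n"
            "p1,Meals,from 6 months,69,3.1,2.2,2.5,0.08\n")
    records, errors = read_products(io.StringIO(text), dialect="nppm_template")
    assert len(errors) == 0
    assert records[0].energy_kcal_100g == 69


def test_roundtrip_is_lossless(small_survey, tmp_path):
    records, _ = small_survey
    path = tmp_path / "products.csv"
    write_products(records, path)
    back, errors = read_products(path)
    assert len(errors) == 0
    assert back == records


def test_roundtrip_frame_is_deterministic(small_survey):
    records, _ = small_survey
    a = records_to_frame(records).to_csv(index=False)
    b = records_to_frame(records).to_csv(index=False)
    assert a == b
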