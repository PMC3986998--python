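"""Nutrient estimation: frequency x portion x composition, the three add-on
rules, the energy formula and energy shares."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiq16.core import encode_features
from fiq16.estimation import (
    EstimationConfig,
    ZeroEnergyError,
    apply_cooking_fat_rule,
    apply_dressing_rule,
    apply_spread_rule,
    compute_energy,
    energy_percent,
    estimate_food_quantities,
    estimate_nutrients,
)


def _with(example, **kw):
    return dataclasses.replace(example, **kw)


# ---------------------------------------------------------------------------
# energy formula and shares


@pytest.mark.parametrize(
    "fat,carb,prot,alc,expected",
    [(10, 0, 0, 0, 370.0), (0, 0, 0, 0, 0.0), (10, 10, 10, 10, 1000.0)],
)
def test_energy_formula(fat, carb, prot, alc, expected):
    assert compute_energy(fat, carb, prot, alc) == expected


def test_energy_rejects_negative():
    with pytest.raises(ValueError):
        compute_energy(-1, 0, 0, 0)


def test_energy_percent_cases():
    # fat-only diet: all energy from fat
    assert energy_percent(10, 37, compute_energy(10, 0, 0, 0)) == pytest.approx(100.0)
    assert energy_percent(0, 17, 540) == 0.0
    # fat 10 g + carbohydrate 10 g: fat share 370/540
    assert energy_percent(10, 37, compute_energy(10, 10, 0, 0)) == pytest.approx(
        370 / 540 * 100
    )
    with pytest.raises(ZeroEnergyError):
        energy_percent(10, 37, 0.0)


# ---------------------------------------------------------------------------
# the three add-on rules


def test_spread_rule(example_response):
    cfg = EstimationConfig(spread_portion_g=5)
    four = _with(
        example_response,
        bread_slices_per_day={"rye_crisp": 3, "multigrain": 0, "white": 1},
    )
    assert apply_spread_rule(four, cfg) == (None, 0.0)  # example uses no spread
    item, g = apply_spread_rule(
        _with(four, spread_on_bread_type="vegetable_margarine"), cfg
    )
    assert (item, g) == ("spread_margarine", 20.0)
    item, g = apply_spread_rule(
        _with(example_response, spread_on_bread_type="butter_or_butter_spread"), cfg
    )
    assert (item, g) == ("spread_butter", 0.0)  # zero bread slices


def test_cooking_fat_rule(example_response):
    cfg = EstimationConfig(cooking_fat_portion_g=10)
    none = _with(example_response, cooking_fat_type="none")
    assert apply_cooking_fat_rule(none, cfg) == (None, 0.0)
    seven = _with(
        example_response,
        dishes_per_week={"fish": 7, "sausage": 0, "chicken": 0, "meat": 0, "vegetable": 0},
    )
    assert apply_cooking_fat_rule(seven, cfg) == ("cooking_oil", 10.0)
    fourteen = _with(
        example_response,
        dishes_per_week={"fish": 7, "sausage": 7, "chicken": 0, "meat": 0, "vegetable": 0},
    )
    assert apply_cooking_fat_rule(fourteen, cfg) == ("cooking_oil", 20.0)


def test_dressing_rule(example_response):
    cfg = EstimationConfig(dressing_portion_g=10)
    assert apply_dressing_rule(example_response, cfg) == (None, 0.0)
    assert apply_dressing_rule(
        _with(example_response, dressing_type="oil_based"), cfg
    ) == ("dressing_oil", 10.0)
    assert apply_dressing_rule(
        _with(example_response, dressing_type="other"), cfg
    ) == ("dressing_other", 10.0)


# ---------------------------------------------------------------------------
# quantities and full estimation


def test_food_quantities(codebook, composition, example_response):
    q = estimate_food_quantities(example_response, codebook, composition)
    assert q["fruit"] == pytest.approx(1.0 * composition["fruit"].portion_g)
    assert q["dish_sausage"] == pytest.approx(2 / 7 * composition["dish_sausage"].portion_g)
    r = _with(
        example_response,
        milk_dl_per_day={"skimmed": 0, "semi_skimmed": 2, "whole": 0},
    )
    q = estimate_food_quantities(r, codebook, composition)
    assert q["milk_semi_skimmed"] == pytest.approx(200.0)  # 1 dl = 100 g


def _zero_response(example):
    zeros = {
        "freq_fastfood": "never",
        "freq_fruit": "none",
        "freq_vegetable": "none",
        "freq_sugar_rich": "never",
        "freq_sweets": "never",
        "cooking_fat_type": "none",
        "cream_in_cooking": "no",
        "spread_on_bread_type": "none",
        "dressing_type": "none",
        "dishes_per_week": dict.fromkeys(example.dishes_per_week, 0.0),
        "milk_dl_per_day": dict.fromkeys(example.milk_dl_per_day, 0.0),
        "cheese_slices_per_day": dict.fromkeys(example.cheese_slices_per_day, 0.0),
        "coldcut_slices_per_day": dict.fromkeys(example.coldcut_slices_per_day, 0.0),
        "bread_slices_per_day": dict.fromkeys(example.bread_slices_per_day, 0.0),
        "cereal_dl_per_day": dict.fromkeys(example.cereal_dl_per_day, 0.0),
        "beverages_per_day": dict.fromkeys(example.beverages_per_day, 0.0),
    }
    return _with(example, **zeros)


def test_zero_response_is_flagged_not_divided(codebook, composition, example_response):
    intake = estimate_nutrients(_zero_response(example_response), codebook, composition)
    assert intake.energy_kj == 0.0
    assert not intake.has_energy
    with pytest.raises(ZeroEnergyError):
        _ = intake.fat_epct


def test_single_item_vitamin_d(codebook, composition, example_response):
    """2 dl of milk at 1 ug vitamin D per 100 g gives 2 ug/day."""
    r = _with(
        _zero_response(example_response),
        milk_dl_per_day={"skimmed": 0, "semi_skimmed": 2, "whole": 0},
    )
    intake = estimate_nutrients(r, codebook, composition)
    assert intake.vitamin_d_ug == pytest.approx(2.0)


def _naive_reference(response, codebook, composition):
    """Independent brute-force re-summation over item quantities."""
    q = estimate_food_quantities(response, codebook, composition)
    out = {}
    for field in ("fat_g", "protein_g", "carbohydrate_g", "sucrose_g", "alcohol_g",
                  "fibre_g", "vitamin_d_ug"):
        total = 0.0
        for item, grams in q.items():
            total += grams * getattr(composition[item], field) / 100.0
        out[field] = total
    out["energy_kj"] = (
        37 * out["fat_g"] + 17 * out["carbohydrate_g"] + 17 * out["protein_g"]
        + 29 * out["alcohol_g"]
    )
    return out


def test_matches_naive_resummation(codebook, composition, small_cohort):
    for r in small_cohort[0][:10]:
        intake = estimate_nutrients(r, codebook, composition)
        ref = _naive_reference(r, codebook, composition)
        for field, val in ref.items():
            assert getattr(intake, field) == pytest.approx(val, abs=1e-9)


def test_energy_share_conservation(codebook, composition, small_cohort, example_response):
    """fat + protein + carbohydrate + alcohol E% = 100 whenever energy > 0."""
    for r in [example_response] + list(small_cohort[0]):
        intake = estimate_nutrients(r, codebook, composition)
        if intake.has_energy:
            total = (
                intake.fat_epct + intake.protein_epct
                + intake.carbohydrate_epct + intake.alcohol_epct
            )
            assert total == pytest.approx(100.0, abs=1e-9)
            assert intake.sucrose_epct <= intake.carbohydrate_epct + 1e-9
            assert intake.saturated_fat_epct <= intake.fat_epct + 1e-9


counts = st.floats(min_value=0, max_value=10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(a=counts, b=counts, extra=st.floats(min_value=0.5, max_value=5))
def test_gram_intakes_additive_and_monotone(a, b, extra):
    """Gram-valued intakes add over responses whose counts add, and never
    decrease when a single count increases."""
    from fiq16 import load_codebook, load_composition
    from fiq16.scoring import example_fat_response

    codebook, composition = load_codebook(), load_composition()
    base = example_fat_response(codebook)

    def with_cheese(x):
        return dataclasses.replace(
            base, cheese_slices_per_day={"low_fat": x, "regular": 0}
        )

    ia = estimate_nutrients(with_cheese(a), codebook, composition)
    ib = estimate_nutrients(with_cheese(b), codebook, composition)
    iab = estimate_nutrients(with_cheese(a + b), codebook, composition)
    base_i = estimate_nutrients(with_cheese(0), codebook, composition)
    # additivity of the cheese contribution
    assert iab.fat_g - base_i.fat_g == pytest.approx(
        (ia.fat_g - base_i.fat_g) + (ib.fat_g - base_i.fat_g), abs=1e-9
    )
    # monotonicity in a single item count
    imore = estimate_nutrients(with_cheese(a + extra), codebook, composition)
    for field in ("fat_g", "protein_g", "carbohydrate_g", "energy_kj", "calcium_mg"):
        assert getattr(imore, field) >= getattr(ia, field) - 1e-12
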