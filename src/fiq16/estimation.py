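"""Nutrient-intake estimation from questionnaire answers.

A response is converted to daily food quantities (grams/day) by multiplying
each item's consumption frequency by the weight of an average portion, with
three add-on rules: spread on bread (one spread portion per reported bread
slice when a spread is used), cooking fat (one cooking-fat portion per
cooked dish, dishes counted per week), and salad dressing (one portion per
day when a dressing is used).  Quantities times composition densities give
daily nutrient grams; energy is the macronutrient formula

    kJ/day = 37*fat_g + 17*carbohydrate_g + 17*protein_g + 29*alcohol_g

and each macronutrient's energy share (E%) is its energy divided by total
energy times 100.  Sucrose is a subset of carbohydrate: it contributes to
total energy once (through carbohydrate) but gets its own E% numerator with
the factor 17 -- double-counting sucrose energy would break the identity
fat + protein + carbohydrate + alcohol E% = 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import (
    BEVERAGE_CLASSES,
    BREAD_CLASSES,
    CEREAL_CLASSES,
    CHEESE_CLASSES,
    COLDCUT_CLASSES,
    DISH_GROUPS,
    MILK_CLASSES,
    Codebook,
    CompositionTable,
    QuestionnaireResponse,
)

logger = logging.getLogger(__name__)

__all__ = [
    "KJ_PER_G_FAT",
    "KJ_PER_G_CARBOHYDRATE",
    "KJ_PER_G_PROTEIN",
    "KJ_PER_G_ALCOHOL",
    "EstimationConfig",
    "NutrientIntake",
    "ZeroEnergyError",
    "estimate_food_quantities",
    "apply_spread_rule",
    "apply_cooking_fat_rule",
    "apply_dressing_rule",
    "compute_energy",
    "energy_percent",
    "estimate_nutrients",
    "estimate_cohort",
]

# Energy conversion factors, kJ per gram.
KJ_PER_G_FAT = 37.0
KJ_PER_G_CARBOHYDRATE = 17.0
KJ_PER_G_PROTEIN = 17.0
KJ_PER_G_SUCROSE = 17.0
KJ_PER_G_ALCOHOL = 29.0


class ZeroEnergyError(ValueError):
    """Energy shares are undefined for a zero-energy intake."""


@dataclass(frozen=True)
class EstimationConfig:
    """Portion sizes for the three add-on rules and the item mapping for
    the type-choice questions.

    Defaults: 5 g of spread per bread slice, 10 g of cooking fat per cooked
    dish, 10 g of cooking cream per cooked dish, 10 g of dressing per use.
    """

    spread_portion_g: float = 5.0
    cooking_fat_portion_g: float = 10.0
    cream_portion_g: float = 10.0
    dressing_portion_g: float = 10.0
    spread_items: dict = field(
        default_factory=lambda: {
            "vegetable_margarine": "spread_margarine",
            "butter_or_butter_spread": "spread_butter",
        }
    )
    cooking_fat_items: dict = field(
        default_factory=lambda: {
            "vegetable_oil_or_margarine": "cooking_oil",
            "butter_or_butter_spread": "cooking_butter",
            "other": "cooking_oil",
        }
    )
    dressing_items: dict = field(
        default_factory=lambda: {"oil_based": "dressing_oil", "other": "dressing_other"}
    )

    def __post_init__(self) -> None:
        for name in ("spread_portion_g", "cooking_fat_portion_g", "cream_portion_g", "dressing_portion_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class NutrientIntake:
    """Estimated daily nutrient intake with energy and energy shares.

    ``energy_kj == 0`` marks a degenerate (all-zero) response: energy shares
    are undefined and accessing them raises :class:`ZeroEnergyError`.
    """

    fat_g: float
    saturated_fat_g: float
    protein_g: float
    carbohydrate_g: float
    sucrose_g: float
    fibre_g: float
    alcohol_g: float
    vitamin_d_ug: float
    vitamin_c_mg: float
    calcium_mg: float
    iron_mg: float
    energy_kj: float

    @property
    def has_energy(self) -> bool:
        return self.energy_kj > 0

    def _epct(self, grams: float, factor: float) -> float:
        return energy_percent(grams, factor, self.energy_kj)

    @property
    def fat_epct(self) -> float:
        return self._epct(self.fat_g, KJ_PER_G_FAT)

    @property
    def saturated_fat_epct(self) -> float:
        return self._epct(self.saturated_fat_g, KJ_PER_G_FAT)

    @property
    def protein_epct(self) -> float:
        return self._epct(self.protein_g, KJ_PER_G_PROTEIN)

    @property
    def carbohydrate_epct(self) -> float:
        return self._epct(self.carbohydrate_g, KJ_PER_G_CARBOHYDRATE)

    @property
    def sucrose_epct(self) -> float:
        return self._epct(self.sucrose_g, KJ_PER_G_SUCROSE)

    @property
    def alcohol_epct(self) -> float:
        return self._epct(self.alcohol_g, KJ_PER_G_ALCOHOL)

    def as_nutrient_row(self) -> dict[str, float]:
        """The 12 comparison variables in report units (E% for macros)."""
        return {
            "energy_kj": self.energy_kj,
            "fat_epct": self.fat_epct,
            "saturated_fat_epct": self.saturated_fat_epct,
            "protein_epct": self.protein_epct,
            "carbohydrate_epct": self.carbohydrate_epct,
            "sucrose_epct": self.sucrose_epct,
            "fibre_g": self.fibre_g,
            "alcohol_epct": self.alcohol_epct,
            "vitamin_d_ug": self.vitamin_d_ug,
            "vitamin_c_mg": self.vitamin_c_mg,
            "calcium_mg": self.calcium_mg,
            "iron_mg": self.iron_mg,
        }


def compute_energy(fat_g: float, carbohydrate_g: float, protein_g: float, alcohol_g: float) -> float:
    """Daily energy in kJ from macronutrient grams (37/17/17/29 factors).

    Sucrose is not an argument: its energy is already inside carbohydrate.
    """
    for name, v in (
        ("fat_g", fat_g),
        ("carbohydrate_g", carbohydrate_g),
        ("protein_g", protein_g),
        ("alcohol_g", alcohol_g),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return (
        KJ_PER_G_FAT * fat_g
        + KJ_PER_G_CARBOHYDRATE * carbohydrate_g
        + KJ_PER_G_PROTEIN * protein_g
        + KJ_PER_G_ALCOHOL * alcohol_g
    )


def energy_percent(nutrient_g: float, kj_per_g: float, total_energy_kj: float) -> float:
    """Energy share E% = grams x factor / total energy x 100."""
    if total_energy_kj <= 0:
        raise ZeroEnergyError("E% is undefined when total energy is zero")
    return nutrient_g * kj_per_g / total_energy_kj * 100.0


def estimate_food_quantities(
    response: QuestionnaireResponse,
    codebook: Codebook,
    composition: CompositionTable,
    config: EstimationConfig | None = None,
) -> dict[str, float]:
    """Daily food quantity (g/day) per composition item, including the
    spread, cooking-fat/cream and dressing rules.

    Frequency answers are converted to per-day rates and multiplied by the
    item's average portion weight; open-ended counts are multiplied by their
    per-unit weight (slice, decilitre, serving).
    """
    config = config or EstimationConfig()
    r = response
    q: dict[str, float] = {}

    def add(item_id: str, grams: float) -> None:
        if item_id not in composition:
            raise KeyError(
                f"no composition entry for item {item_id!r}; "
                "the composition table must cover every questionnaire item"
            )
        q[item_id] = q.get(item_id, 0.0) + grams

    def portion(item_id: str) -> float:
        return composition[item_id].portion_g

    add("meal_average", codebook.daily_rate("meals_per_day", r.meals_per_day) * portion("meal_average"))
    add("fastfood", codebook.daily_rate("fastfood", r.freq_fastfood) * portion("fastfood"))
    add("fruit", codebook.daily_rate("fruit", r.freq_fruit) * portion("fruit"))
    add("vegetable", codebook.daily_rate("vegetable", r.freq_vegetable) * portion("vegetable"))
    add("sugar_rich", codebook.daily_rate("sugar_rich", r.freq_sugar_rich) * portion("sugar_rich"))
    add("sweets", codebook.daily_rate("sweets", r.freq_sweets) * portion("sweets"))

    for g in DISH_GROUPS:
        add(f"dish_{g}", r.dishes_per_week[g] / 7.0 * portion(f"dish_{g}"))
    for c in MILK_CLASSES:
        add(f"milk_{c}", r.milk_dl_per_day[c] * portion(f"milk_{c}"))
    for c in CHEESE_CLASSES:
        add(f"cheese_{c}", r.cheese_slices_per_day[c] * portion(f"cheese_{c}"))
    for c in COLDCUT_CLASSES:
        add(f"coldcut_{c}", r.coldcut_slices_per_day[c] * portion(f"coldcut_{c}"))
    bread_items = {"rye_crisp": "bread_rye", "multigrain": "bread_multigrain", "white": "bread_white"}
    for c in BREAD_CLASSES:
        add(bread_items[c], r.bread_slices_per_day[c] * portion(bread_items[c]))
    for c in CEREAL_CLASSES:
        add(f"cereal_{c}", r.cereal_dl_per_day[c] * portion(f"cereal_{c}"))
    for c in BEVERAGE_CLASSES:
        add(f"bev_{c}", r.beverages_per_day[c] * portion(f"bev_{c}"))

    spread_item, spread_g = apply_spread_rule(r, config)
    if spread_item is not None:
        add(spread_item, spread_g)
    fat_item, fat_g = apply_cooking_fat_rule(r, config)
    if fat_item is not None:
        add(fat_item, fat_g)
    if r.cream_in_cooking == "yes":
        dishes = sum(r.dishes_per_week.values())
        add("cooking_cream", dishes / 7.0 * config.cream_portion_g)
    dressing_item, dressing_g = apply_dressing_rule(r, config)
    if dressing_item is not None:
        add(dressing_item, dressing_g)
    return q


def apply_spread_rule(
    response: QuestionnaireResponse, config: EstimationConfig | None = None
) -> tuple[str | None, float]:
    """Spread on bread: one spread portion per reported bread slice, typed
    margarine vs butter; zero when no spread is used."""
    config = config or EstimationConfig()
    if response.spread_on_bread_type == "none":
        return None, 0.0
    slices = sum(response.bread_slices_per_day.values())
    item = config.spread_items[response.spread_on_bread_type]
    return item, slices * config.spread_portion_g


def apply_cooking_fat_rule(
    response: QuestionnaireResponse, config: EstimationConfig | None = None
) -> tuple[str | None, float]:
    """Cooking fat: one fat portion per cooked dish (dishes counted per
    week, converted to per day), typed by the reported cooking fat."""
    config = config or EstimationConfig()
    if response.cooking_fat_type == "none":
        return None, 0.0
    dishes_per_week = sum(response.dishes_per_week.values())
    item = config.cooking_fat_items[response.cooking_fat_type]
    return item, dishes_per_week / 7.0 * config.cooking_fat_portion_g


def apply_dressing_rule(
    response: QuestionnaireResponse, config: EstimationConfig | None = None
) -> tuple[str | None, float]:
    """Salad dressing: one average portion per day when a dressing is used."""
    config = config or EstimationConfig()
    if response.dressing_type == "none":
        return None, 0.0
    item = config.dressing_items[response.dressing_type]
    return item, config.dressing_portion_g


def estimate_nutrients(
    response: QuestionnaireResponse,
    codebook: Codebook,
    composition: CompositionTable,
    config: EstimationConfig | None = None,
) -> NutrientIntake:
    """Estimate a full daily :class:`NutrientIntake` for one response."""
    quantities = estimate_food_quantities(response, codebook, composition, config)
    totals = dict.fromkeys(
        (
            "fat_g",
            "saturated_fat_g",
            "protein_g",
            "carbohydrate_g",
            "sucrose_g",
            "fibre_g",
            "alcohol_g",
            "vitamin_d_ug",
            "vitamin_c_mg",
            "calcium_mg",
            "iron_mg",
        ),
        0.0,
    )
    for item_id, grams in quantities.items():
        entry = composition[item_id]
        for k in totals:
            totals[k] += grams * getattr(entry, k) / 100.0
    energy = compute_energy(
        totals["fat_g"], totals["carbohydrate_g"], totals["protein_g"], totals["alcohol_g"]
    )
    if energy == 0:
        logger.warning(
            "participant %s: zero-energy response, E%% undefined", response.participant_id
        )
    return NutrientIntake(energy_kj=energy, **totals)


def estimate_cohort(
    responses,
    codebook: Codebook,
    composition: CompositionTable,
    config: EstimationConfig | None = None,
) -> pd.DataFrame:
    """Per-participant nutrient-intake table (one row per participant).

    Zero-energy responses are kept but flagged (``flag == 'zero_energy'``)
    with E% columns set to NaN; downstream comparisons skip flagged rows.
    """
    rows = []
    for r in responses:
        intake = estimate_nutrients(r, codebook, composition, config)
        row: dict[str, object] = {"participant_id": r.participant_id}
        if intake.has_energy:
            row.update(intake.as_nutrient_row())
            row["flag"] = ""
        else:
            row.update(
                {
                    "energy_kj": 0.0,
                    "fibre_g": intake.fibre_g,
                    "vitamin_d_ug": intake.vitamin_d_ug,
                    "vitamin_c_mg": intake.vitamin_c_mg,
                    "calcium_mg": intake.calcium_mg,
                    "iron_mg": intake.iron_mg,
                }
            )
            row["flag"] = "zero_energy"
        rows.append(row)
    df = pd.DataFrame(rows)
    ordered = ["participant_id", "energy_kj", "fat_epct", "saturated_fat_epct", "protein_epct",
               "carbohydrate_epct", "sucrose_epct", "fibre_g", "alcohol_epct", "vitamin_d_ug",
               "vitamin_c_mg", "calcium_mg", "iron_mg", "flag"]
    for c in ordered:
        if c not in df.columns:
            df[c] = pd.NA
    return df[ordered]
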