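"""Synthetic paired questionnaire/food-record cohorts.

The generator emulates the measurement structure a short-questionnaire
validation study assumes: each participant has a latent habitual intake per
food group, the 7-day food record observes it through day-to-day variation
averaged over seven days, and the questionnaire observes it through
reporting noise plus the coarsening of answers into categories and counts.

Latent intakes are log-normal (dietary intakes are right-skewed, and a
log-normal latent gives the log-transform option downstream something real
to correct).  For a target rank correlation ``r_s`` between the two
instruments, the reporting-noise SD is solved analytically from the
bivariate-normal relation ``r_s = (6/pi) * asin(rho/2)`` between the
Pearson correlation ``rho`` of the latent log scales and the Spearman
correlation of the observed values; answer coarsening attenuates the
realized value slightly below the target.

Defaults are the study conditions: n = 77 with the 52:25 male:female split,
and per-group target correlations equal to the validation study's printed
per-group values (0.08-0.75).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    BEVERAGE_CLASSES,
    FOOD_GROUPS,
    Codebook,
    CompositionTable,
    FoodRecordSummary,
    QuestionnaireResponse,
    load_codebook,
    load_composition,
)
from .estimation import compute_energy, energy_percent, KJ_PER_G_ALCOHOL, KJ_PER_G_CARBOHYDRATE, KJ_PER_G_FAT, KJ_PER_G_PROTEIN, KJ_PER_G_SUCROSE
from .models import FitDataset

__all__ = ["GroupSpec", "CohortSpec", "generate_cohort", "generate_known_model_data"]


@dataclass(frozen=True)
class GroupSpec:
    """Latent-intake parameters for one food group.

    ``log_mean``/``log_sd`` parameterize the log-normal latent consumption
    frequency (events/day in the group's questionnaire unit); ``target_rs``
    is the rank correlation the generator aims for between questionnaire
    and record.  ``reporting_sd`` overrides the analytically solved
    reporting-noise SD when given.
    """

    log_mean: float
    log_sd: float = 0.7
    target_rs: float = 0.5
    reporting_sd: float | None = None

    def __post_init__(self) -> None:
        if self.log_sd < 0:
            raise ValueError("log_sd must be >= 0")
        if not -1.0 <= self.target_rs <= 1.0:
            raise ValueError("target_rs must be in [-1, 1]")


# Mean daily frequencies (log scale) chosen once as realistic for a Nordic
# working-age cohort; target correlations are the validation study's
# per-group values.
_DEFAULT_GROUPS: dict[str, GroupSpec] = {
    "fish_dishes": GroupSpec(math.log(0.29), 0.7, 0.57),
    "sausage_dishes": GroupSpec(math.log(0.21), 0.7, 0.14),
    "poultry_dishes": GroupSpec(math.log(0.21), 0.7, 0.08),
    "meat_dishes": GroupSpec(math.log(0.43), 0.7, 0.28),
    "vegetable_dishes": GroupSpec(math.log(0.29), 0.7, 0.35),
    "fast_foods": GroupSpec(math.log(0.10), 0.8, 0.13),
    "vegetables": GroupSpec(math.log(1.5), 0.6, 0.36),
    "fruits_and_berries": GroupSpec(math.log(1.2), 0.7, 0.65),
    "milk_products": GroupSpec(math.log(4.0), 0.6, 0.68),
    "rye_breads": GroupSpec(math.log(2.5), 0.7, 0.59),
    "multigrain_breads": GroupSpec(math.log(1.0), 0.7, 0.29),
    "white_breads": GroupSpec(math.log(0.7), 0.7, 0.42),
    "porridges": GroupSpec(math.log(0.5), 0.8, 0.65),
    "breakfast_cereals": GroupSpec(math.log(0.3), 0.8, 0.63),
    "cheeses": GroupSpec(math.log(3.0), 0.6, 0.39),
    "cold_cuts": GroupSpec(math.log(2.5), 0.7, 0.46),
    "desserts": GroupSpec(math.log(0.5), 0.7, 0.57),
    "sweets_and_sugar": GroupSpec(math.log(0.7), 0.7, 0.48),
    "tea": GroupSpec(math.log(1.0), 1.0, 0.75),
    "coffee": GroupSpec(math.log(3.0), 0.6, 0.58),
    "soft_drinks": GroupSpec(math.log(0.3), 0.9, 0.49),
    "sugar_sweetened_juices": GroupSpec(math.log(0.3), 0.9, 0.42),
    "fruit_juices": GroupSpec(math.log(0.5), 0.9, 0.51),
    "beer": GroupSpec(math.log(0.4), 1.0, 0.61),
    "wine": GroupSpec(math.log(0.3), 1.0, 0.74),
    "distilled_spirits": GroupSpec(math.log(0.1), 1.0, 0.33),
}

#: Composition item whose densities stand in for each record food group.
GROUP_COMPOSITION_ITEM: dict[str, str] = {
    "fish_dishes": "dish_fish",
    "sausage_dishes": "dish_sausage",
    "poultry_dishes": "dish_chicken",
    "meat_dishes": "dish_meat",
    "vegetable_dishes": "dish_vegetable",
    "fast_foods": "fastfood",
    "vegetables": "vegetable",
    "fruits_and_berries": "fruit",
    "milk_products": "milk_semi_skimmed",
    "rye_breads": "bread_rye",
    "multigrain_breads": "bread_multigrain",
    "white_breads": "bread_white",
    "porridges": "cereal_porridge",
    "breakfast_cereals": "cereal_other",
    "cheeses": "cheese_regular",
    "cold_cuts": "coldcut_regular",
    "desserts": "sugar_rich",
    "sweets_and_sugar": "sweets",
    "tea": "bev_tea",
    "coffee": "bev_coffee",
    "soft_drinks": "bev_soft_drink",
    "sugar_sweetened_juices": "bev_sugar_sweetened_juice",
    "fruit_juices": "bev_fruit_juice",
    "beer": "bev_beer",
    "wine": "bev_wine",
    "distilled_spirits": "bev_spirits",
}


@dataclass
class CohortSpec:
    """Specification of a synthetic paired cohort.

    ``day_sd`` is the within-person day-to-day SD on the log scale (the
    record averages 7 such days); ``male_fraction`` defaults to the study's
    52:25 split.
    """

    n: int = 77
    seed: int = 0
    male_fraction: float = 52 / 77
    day_sd: float = 0.8
    record_days: int = 7
    groups: dict[str, GroupSpec] = field(default_factory=lambda: dict(_DEFAULT_GROUPS))

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.day_sd < 0:
            raise ValueError("day_sd must be >= 0")
        missing = set(FOOD_GROUPS) - set(self.groups)
        if missing:
            raise ValueError(f"missing group specs: {sorted(missing)}")

    def with_target(self, group: str, target_rs: float) -> "CohortSpec":
        """A copy with one group's target rank correlation replaced."""
        groups = dict(self.groups)
        groups[group] = replace(groups[group], target_rs=target_rs)
        return replace(self, groups=groups)


def _reporting_sd(gspec: GroupSpec, day_sd: float, record_days: int) -> float:
    """Reporting-noise SD (log scale) that targets the group's rank
    correlation, given the record-side day-to-day attenuation."""
    if gspec.reporting_sd is not None:
        return gspec.reporting_sd
    rs = gspec.target_rs
    if rs <= 0:  # independence or worse: blow up the noise
        return 10.0
    rho = 2.0 * math.sin(math.pi * rs / 6.0)
    lat_var = gspec.log_sd**2
    if lat_var == 0:
        return 0.0
    # log-variance of the mean of `record_days` multiplicative day factors
    rec_var = math.log1p((math.exp(day_sd**2) - 1.0) / record_days)
    max_rho2 = lat_var / (lat_var + rec_var)
    if rho**2 >= max_rho2:
        return 0.0  # target unreachable given day noise; best effort
    q_var = lat_var**2 / (rho**2 * (lat_var + rec_var)) - lat_var
    return math.sqrt(max(q_var, 0.0))


def _nearest_category(codebook: Codebook, item_id: str, rate_per_day: float) -> str:
    cats = codebook[item_id].categories
    return min(cats, key=lambda c: abs(c.daily_rate - rate_per_day)).label


def generate_cohort(
    spec: CohortSpec,
    codebook: Codebook | None = None,
    composition: CompositionTable | None = None,
) -> tuple[list[QuestionnaireResponse], list[FoodRecordSummary]]:
    """Generate a paired synthetic cohort, deterministic given ``spec.seed``.

    Returns responses (valid against the codebook) and food-record
    summaries whose nutrient intakes are exactly the composition mapping
    applied to the generated food-group grams.
    """
    codebook = codebook or load_codebook()
    composition = composition or load_composition()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    # latent frequencies and both observations, per group
    record_freq: dict[str, np.ndarray] = {}
    quest_freq: dict[str, np.ndarray] = {}
    for g in FOOD_GROUPS:
        gs = spec.groups[g]
        latent = np.exp(gs.log_mean + gs.log_sd * rng.standard_normal(n))
        day_factors = np.exp(
            spec.day_sd * rng.standard_normal((n, spec.record_days)) - spec.day_sd**2 / 2
        )
        record_freq[g] = latent * day_factors.mean(axis=1)
        s_q = _reporting_sd(gs, spec.day_sd, spec.record_days)
        quest_freq[g] = latent * np.exp(s_q * rng.standard_normal(n))

    n_male = int(round(n * spec.male_fraction))
    sexes = ["male"] * n_male + ["female"] * (n - n_male)

    milk_class = rng.choice(["skimmed", "semi_skimmed", "whole"], size=n, p=[0.3, 0.5, 0.2])
    cheese_class = rng.choice(["low_fat", "regular"], size=n, p=[0.4, 0.6])
    coldcut_class = rng.choice(["low_fat", "regular"], size=n, p=[0.4, 0.6])
    frank_share = rng.choice([0.0, 0.25], size=n, p=[0.7, 0.3])
    cooking_fat = rng.choice(
        ["vegetable_oil_or_margarine", "butter_or_butter_spread", "none", "other"],
        size=n, p=[0.6, 0.3, 0.05, 0.05],
    )
    cream = rng.choice(["yes", "no"], size=n, p=[0.3, 0.7])
    spread = rng.choice(
        ["vegetable_margarine", "butter_or_butter_spread", "none"], size=n, p=[0.5, 0.3, 0.2]
    )
    dressing = rng.choice(["oil_based", "other", "none"], size=n, p=[0.5, 0.2, 0.3])
    meals = rng.choice(["1-2", "3-4", "5-6", "7_or_more"], size=n, p=[0.15, 0.55, 0.25, 0.05])

    def count(g: str, i: int, scale: float = 1.0, step: float = 1.0, cap: float = 30.0) -> float:
        v = quest_freq[g][i] * scale
        return float(np.clip(np.round(v / step) * step, 0.0, cap))

    responses: list[QuestionnaireResponse] = []
    records: list[FoodRecordSummary] = []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        milk_total = count("milk_products", i, step=0.5, cap=15.0)
        cheese_total = count("cheeses", i, cap=20.0)
        coldcut_total = count("cold_cuts", i, cap=20.0)
        franks = float(np.round(coldcut_total * frank_share[i]))
        coldcut_rest = coldcut_total - franks
        responses.append(
            QuestionnaireResponse(
                participant_id=pid,
                sex=sexes[i],
                meals_per_day=str(meals[i]),
                freq_fastfood=_nearest_category(codebook, "fastfood", quest_freq["fast_foods"][i]),
                freq_fruit=_nearest_category(codebook, "fruit", quest_freq["fruits_and_berries"][i]),
                freq_vegetable=_nearest_category(codebook, "vegetable", quest_freq["vegetables"][i]),
                freq_sugar_rich=_nearest_category(codebook, "sugar_rich", quest_freq["desserts"][i]),
                freq_sweets=_nearest_category(codebook, "sweets", quest_freq["sweets_and_sugar"][i]),
                cooking_fat_type=str(cooking_fat[i]),
                cream_in_cooking=str(cream[i]),
                spread_on_bread_type=str(spread[i]),
                dressing_type=str(dressing[i]),
                dishes_per_week={
                    "fish": count("fish_dishes", i, scale=7.0, cap=28.0),
                    "sausage": count("sausage_dishes", i, scale=7.0, cap=28.0),
                    "chicken": count("poultry_dishes", i, scale=7.0, cap=28.0),
                    "meat": count("meat_dishes", i, scale=7.0, cap=28.0),
                    "vegetable": count("vegetable_dishes", i, scale=7.0, cap=28.0),
                },
                milk_dl_per_day={
                    c: (milk_total if c == milk_class[i] else 0.0)
                    for c in ("skimmed", "semi_skimmed", "whole")
                },
                cheese_slices_per_day={
                    c: (cheese_total if c == cheese_class[i] else 0.0)
                    for c in ("low_fat", "regular")
                },
                coldcut_slices_per_day={
                    "low_fat": coldcut_rest if coldcut_class[i] == "low_fat" else 0.0,
                    "regular": coldcut_rest if coldcut_class[i] == "regular" else 0.0,
                    "frankfurter": franks,
                },
                bread_slices_per_day={
                    "rye_crisp": count("rye_breads", i, cap=20.0),
                    "multigrain": count("multigrain_breads", i, cap=20.0),
                    "white": count("white_breads", i, cap=20.0),
                },
                cereal_dl_per_day={
                    "porridge": count("porridges", i, step=0.5, cap=10.0),
                    "other": count("breakfast_cereals", i, step=0.5, cap=10.0),
                },
                beverages_per_day={
                    "tea": count("tea", i, cap=15.0),
                    "coffee": count("coffee", i, cap=15.0),
                    "soft_drink": count("soft_drinks", i, cap=10.0),
                    "sugar_sweetened_juice": count("sugar_sweetened_juices", i, cap=10.0),
                    "fruit_juice": count("fruit_juices", i, cap=10.0),
                    "beer": count("beer", i, cap=10.0),
                    "wine": count("wine", i, cap=10.0),
                    "spirits": count("distilled_spirits", i, cap=10.0),
                },
            )
        )
        grams = {
            g: float(record_freq[g][i] * composition[GROUP_COMPOSITION_ITEM[g]].portion_g)
            for g in FOOD_GROUPS
        }
        records.append(
            FoodRecordSummary(
                participant_id=pid,
                food_group_g_per_day=grams,
                nutrients=record_nutrients(grams, composition),
            )
        )
    return responses, records


def record_nutrients(
    food_group_g_per_day: Mapping[str, float], composition: CompositionTable
) -> dict[str, float]:
    """Nutrient variables implied by food-group grams via the composition
    mapping (the generator's internal conservation contract)."""
    totals = dict.fromkeys(
        ("fat_g", "saturated_fat_g", "protein_g", "carbohydrate_g", "sucrose_g",
         "fibre_g", "alcohol_g", "vitamin_d_ug", "vitamin_c_mg", "calcium_mg", "iron_mg"),
        0.0,
    )
    for g, grams in food_group_g_per_day.items():
        entry = composition[GROUP_COMPOSITION_ITEM[g]]
        for k in totals:
            totals[k] += grams * getattr(entry, k) / 100.0
    energy = compute_energy(
        totals["fat_g"], totals["carbohydrate_g"], totals["protein_g"], totals["alcohol_g"]
    )
    return {
        "energy_kj": energy,
        "fat_epct": energy_percent(totals["fat_g"], KJ_PER_G_FAT, energy),
        "saturated_fat_epct": energy_percent(totals["saturated_fat_g"], KJ_PER_G_FAT, energy),
        "protein_epct": energy_percent(totals["protein_g"], KJ_PER_G_PROTEIN, energy),
        "carbohydrate_epct": energy_percent(totals["carbohydrate_g"], KJ_PER_G_CARBOHYDRATE, energy),
        "sucrose_epct": energy_percent(totals["sucrose_g"], KJ_PER_G_SUCROSE, energy),
        "fibre_g": totals["fibre_g"],
        "alcohol_epct": energy_percent(totals["alcohol_g"], KJ_PER_G_ALCOHOL, energy),
        "vitamin_d_ug": totals["vitamin_d_ug"],
        "vitamin_c_mg": totals["vitamin_c_mg"],
        "calcium_mg": totals["calcium_mg"],
        "iron_mg": totals["iron_mg"],
    }


def generate_known_model_data(
    n: int,
    true_multipliers: Mapping[str, int] | Sequence[int],
    intercept: float,
    slope: float,
    noise_sd: float,
    seed: int,
) -> FitDataset:
    """Parameter-recovery harness: item values with a known integer-weighted
    linear target plus Gaussian noise.

    Item values are drawn uniformly from 0-7 (codebook-plausible weekly
    counts); target = intercept + slope * sum(m_i x_i) + N(0, noise_sd).
    """
    if isinstance(true_multipliers, Mapping):
        names = list(true_multipliers)
        m = np.array([true_multipliers[k] for k in names], dtype=float)
    else:
        m = np.asarray(true_multipliers, dtype=float)
        names = [f"item_{chr(ord('a') + j)}" for j in range(m.size)]
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 8, size=(n, m.size)).astype(float)
    y = intercept + slope * (X @ m) + noise_sd * rng.standard_normal(n)
    return FitDataset(
        X=pd.DataFrame(X, columns=names),
        y=pd.Series(y, name="target"),
        nutrient_id="synthetic",
        unit="",
    )
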