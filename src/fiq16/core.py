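"""Domain types and the canonical codebook for the 16-item food intake
questionnaire (16-FIQ).

The 16-FIQ is a short dietary screener with three question types:

* six categorical frequency questions (meals per day; fast food, fruit,
  vegetable, sugar-rich food and sweets consumption frequency),
* four type-choice questions (fat or cream used for cooking, spread used on
  bread, type of salad dressing),
* six open-ended quantity questions (weekly dish counts for five dish
  groups; daily milk decilitres, cheese and cold-cut slices split by fat
  class, bread slices and breakfast-cereal decilitres split by fibre class,
  and beverage servings split by sugar/alcohol class).

Everything downstream (nutrient estimation, validation statistics, scoring
models) consumes the types defined here.  The exact answer categories of the
original instrument live in an unreproduced supplementary file, so the
packaged codebook is a documented, replaceable stand-in: it covers every
category named in the published methods and worked example, and a future
exact transcription drops in as configuration without code change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "DISH_GROUPS",
    "MILK_CLASSES",
    "CHEESE_CLASSES",
    "COLDCUT_CLASSES",
    "BREAD_CLASSES",
    "CEREAL_CLASSES",
    "BEVERAGE_CLASSES",
    "SEXES",
    "COOKING_FAT_TYPES",
    "CREAM_IN_COOKING",
    "SPREAD_TYPES",
    "DRESSING_TYPES",
    "FOOD_GROUPS",
    "NUTRIENTS",
    "ITEM_IDS",
    "CodebookError",
    "ResponseError",
    "Category",
    "ItemSpec",
    "Codebook",
    "load_codebook",
    "frequency_to_daily",
    "QuestionnaireResponse",
    "CompositionEntry",
    "CompositionTable",
    "load_composition",
    "encode_features",
    "questionnaire_frequencies",
    "read_responses",
    "write_responses",
    "FoodRecordSummary",
    "read_food_records",
    "write_food_records",
]

# ---------------------------------------------------------------------------
# Controlled vocabularies

DISH_GROUPS = ("fish", "sausage", "chicken", "meat", "vegetable")
MILK_CLASSES = ("skimmed", "semi_skimmed", "whole")
CHEESE_CLASSES = ("low_fat", "regular")
COLDCUT_CLASSES = ("low_fat", "regular", "frankfurter")
BREAD_CLASSES = ("rye_crisp", "multigrain", "white")
CEREAL_CLASSES = ("porridge", "other")
BEVERAGE_CLASSES = (
    "tea",
    "coffee",
    "soft_drink",
    "sugar_sweetened_juice",
    "fruit_juice",
    "beer",
    "wine",
    "spirits",
)

SEXES = ("male", "female")
COOKING_FAT_TYPES = ("vegetable_oil_or_margarine", "butter_or_butter_spread", "none", "other")
CREAM_IN_COOKING = ("yes", "no")
SPREAD_TYPES = ("vegetable_margarine", "butter_or_butter_spread", "none")
DRESSING_TYPES = ("oil_based", "other", "none")

#: The 26 food groups of the 7-day food-record reference method.
FOOD_GROUPS = (
    "fish_dishes",
    "sausage_dishes",
    "poultry_dishes",
    "meat_dishes",
    "vegetable_dishes",
    "fast_foods",
    "vegetables",
    "fruits_and_berries",
    "milk_products",
    "rye_breads",
    "multigrain_breads",
    "white_breads",
    "porridges",
    "breakfast_cereals",
    "cheeses",
    "cold_cuts",
    "desserts",
    "sweets_and_sugar",
    "tea",
    "coffee",
    "soft_drinks",
    "sugar_sweetened_juices",
    "fruit_juices",
    "beer",
    "wine",
    "distilled_spirits",
)

#: The 12 nutrient variables compared between the two instruments, in the
#: units the validation reports them (energy-percent for macronutrients).
NUTRIENTS = (
    "energy_kj",
    "fat_epct",
    "saturated_fat_epct",
    "protein_epct",
    "carbohydrate_epct",
    "sucrose_epct",
    "fibre_g",
    "alcohol_epct",
    "vitamin_d_ug",
    "vitamin_c_mg",
    "calcium_mg",
    "iron_mg",
)

#: The 16 questionnaire items.
ITEM_IDS = (
    "meals_per_day",
    "fastfood",
    "fruit",
    "vegetable",
    "sugar_rich",
    "sweets",
    "cooking_fat",
    "cream_in_cooking",
    "spread",
    "dressing",
    "dishes",
    "milk",
    "cheese",
    "coldcuts",
    "bread_and_cereals",
    "beverages",
)

_PERIOD_DAYS = {"day": 1.0, "week": 7.0, "month": 30.0}


class CodebookError(ValueError):
    """Raised when a codebook document violates the codebook contract."""


class ResponseError(ValueError):
    """Raised when a questionnaire response is incomplete or invalid."""


# ---------------------------------------------------------------------------
# Codebook


@dataclass(frozen=True)
class Category:
    """One answer category of an ordinal frequency item.

    ``midpoint`` is the numeric midpoint of the category in events per
    ``per`` (day, week or month); the daily rate is ``midpoint`` divided by
    the period length (7 for weekly, 30 for monthly categories).
    """

    label: str
    midpoint: float
    per: str = "day"

    @property
    def daily_rate(self) -> float:
        return self.midpoint / _PERIOD_DAYS[self.per]


@dataclass(frozen=True)
class ItemSpec:
    """Specification of one questionnaire item.

    ``kind`` is ``ordinal`` (categorical frequency), ``choice`` (type
    selection) or ``count`` (open-ended quantity, possibly split into
    classes).
    """

    item_id: str
    kind: str
    unit: str = ""
    categories: tuple[Category, ...] = ()
    choices: tuple[str, ...] = ()
    classes: tuple[str, ...] = ()

    def category(self, label: str) -> Category:
        for cat in self.categories:
            if cat.label == label:
                return cat
        raise CodebookError(
            f"item {self.item_id!r}: unknown category {label!r} "
            f"(allowed: {[c.label for c in self.categories]})"
        )


@dataclass(frozen=True)
class Codebook:
    """The validated set of 16 item specifications."""

    items: Mapping[str, ItemSpec]
    version: int = 1

    def __getitem__(self, item_id: str) -> ItemSpec:
        try:
            return self.items[item_id]
        except KeyError:
            raise CodebookError(f"unknown questionnaire item {item_id!r}") from None

    def daily_rate(self, item_id: str, label: str) -> float:
        return self[item_id].category(label).daily_rate


def _parse_item(item_id: str, raw: Mapping) -> ItemSpec:
    kind = raw.get("kind")
    if kind not in ("ordinal", "choice", "count"):
        raise CodebookError(f"item {item_id!r}: unknown kind {kind!r}")
    if kind == "ordinal":
        cats = []
        seen = set()
        for c in raw.get("categories", ()):
            cat = Category(str(c["label"]), float(c["midpoint"]), str(c.get("per", "day")))
            if cat.per not in _PERIOD_DAYS:
                raise CodebookError(f"item {item_id!r}: unknown period {cat.per!r}")
            if cat.label in seen:
                raise CodebookError(f"item {item_id!r}: duplicate category {cat.label!r}")
            seen.add(cat.label)
            cats.append(cat)
        if len(cats) < 2:
            raise CodebookError(f"item {item_id!r}: needs at least two categories")
        rates = [c.daily_rate for c in cats]
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise CodebookError(
                f"item {item_id!r}: category midpoints are not strictly increasing "
                f"on the per-day scale"
            )
        return ItemSpec(item_id, kind, str(raw.get("unit", "")), categories=tuple(cats))
    if kind == "choice":
        choices = tuple(str(c) for c in raw.get("choices", ()))
        if len(choices) < 2:
            raise CodebookError(f"item {item_id!r}: needs at least two choices")
        return ItemSpec(item_id, kind, str(raw.get("unit", "")), choices=choices)
    classes = tuple(str(c) for c in raw.get("classes", ()))
    return ItemSpec(item_id, kind, str(raw.get("unit", "")), classes=classes)


def load_codebook(source: str | Path | None = None) -> Codebook:
    """Load and validate a codebook from a YAML document.

    With ``source=None`` the packaged default codebook is loaded.  The
    document must define all 16 items; ordinal items must have strictly
    increasing per-day midpoints and unique category labels.
    """
    if source is None:
        text = resources.files("fiq16.data").joinpath("codebook.yaml").read_text()
    else:
        text = Path(source).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "items" not in doc:
        raise CodebookError("codebook document must be a mapping with an 'items' key")
    raw_items = doc["items"]
    missing = [i for i in ITEM_IDS if i not in raw_items]
    if missing:
        raise CodebookError(f"missing item(s): {', '.join(missing)}")
    extra = [i for i in raw_items if i not in ITEM_IDS]
    if extra:
        raise CodebookError(f"unknown item(s): {', '.join(extra)}")
    items = {iid: _parse_item(iid, raw_items[iid]) for iid in ITEM_IDS}
    return Codebook(items=items, version=int(doc.get("version", 1)))


def frequency_to_daily(codebook: Codebook, item_id: str, label: str) -> float:
    """Convert an ordinal category to its per-day rate.

    Weekly midpoints are divided by 7, monthly by 30.
    """
    return codebook.daily_rate(item_id, label)


# ---------------------------------------------------------------------------
# Questionnaire response


def _check_counts(name: str, values: Mapping[str, float], keys: Iterable[str]) -> None:
    keys = tuple(keys)
    if set(values) != set(keys):
        raise ResponseError(
            f"{name}: expected classes {sorted(keys)}, got {sorted(values)}"
        )
    for k, v in values.items():
        if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
            raise ResponseError(f"{name}[{k}]: must be a finite nonnegative number, got {v!r}")


@dataclass
class QuestionnaireResponse:
    """One participant's complete, encoded 16-FIQ answers plus sex.

    Sex is not one of the 16 food items but is carried on the response
    because the published scoring models use it.  A response must be
    complete; missing answers are a hard error at construction or load time.
    """

    participant_id: str
    sex: str
    meals_per_day: str
    freq_fastfood: str
    freq_fruit: str
    freq_vegetable: str
    freq_sugar_rich: str
    freq_sweets: str
    cooking_fat_type: str
    cream_in_cooking: str
    spread_on_bread_type: str
    dressing_type: str
    dishes_per_week: dict[str, float]
    milk_dl_per_day: dict[str, float]
    cheese_slices_per_day: dict[str, float]
    coldcut_slices_per_day: dict[str, float]
    bread_slices_per_day: dict[str, float]
    cereal_dl_per_day: dict[str, float]
    beverages_per_day: dict[str, float]

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ResponseError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.cooking_fat_type not in COOKING_FAT_TYPES:
            raise ResponseError(f"cooking_fat_type: invalid value {self.cooking_fat_type!r}")
        if self.cream_in_cooking not in CREAM_IN_COOKING:
            raise ResponseError(f"cream_in_cooking: invalid value {self.cream_in_cooking!r}")
        if self.spread_on_bread_type not in SPREAD_TYPES:
            raise ResponseError(
                f"spread_on_bread_type: invalid value {self.spread_on_bread_type!r}"
            )
        if self.dressing_type not in DRESSING_TYPES:
            raise ResponseError(f"dressing_type: invalid value {self.dressing_type!r}")
        _check_counts("dishes_per_week", self.dishes_per_week, DISH_GROUPS)
        _check_counts("milk_dl_per_day", self.milk_dl_per_day, MILK_CLASSES)
        _check_counts("cheese_slices_per_day", self.cheese_slices_per_day, CHEESE_CLASSES)
        _check_counts("coldcut_slices_per_day", self.coldcut_slices_per_day, COLDCUT_CLASSES)
        _check_counts("bread_slices_per_day", self.bread_slices_per_day, BREAD_CLASSES)
        _check_counts("cereal_dl_per_day", self.cereal_dl_per_day, CEREAL_CLASSES)
        _check_counts("beverages_per_day", self.beverages_per_day, BEVERAGE_CLASSES)

    def validate_against(self, codebook: Codebook) -> None:
        """Check that every categorical answer is a codebook category."""
        codebook.daily_rate("meals_per_day", self.meals_per_day)
        codebook.daily_rate("fastfood", self.freq_fastfood)
        codebook.daily_rate("fruit", self.freq_fruit)
        codebook.daily_rate("vegetable", self.freq_vegetable)
        codebook.daily_rate("sugar_rich", self.freq_sugar_rich)
        codebook.daily_rate("sweets", self.freq_sweets)


# ---------------------------------------------------------------------------
# Composition table

_DENSITY_FIELDS = (
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
)


@dataclass(frozen=True)
class CompositionEntry:
    """Average portion weight and nutrient densities (per 100 g) for one
    questionnaire food item."""

    item_id: str
    portion_g: float
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

    def __post_init__(self) -> None:
        if self.portion_g <= 0:
            raise ValueError(f"{self.item_id}: portion weight must be positive")
        for f in _DENSITY_FIELDS:
            if getattr(self, f) < 0:
                raise ValueError(f"{self.item_id}: negative density {f}")
        macro = self.fat_g + self.protein_g + self.carbohydrate_g + self.alcohol_g
        if macro > 100 + 1e-9:
            raise ValueError(f"{self.item_id}: macronutrients exceed 100 g per 100 g")
        if self.sucrose_g > self.carbohydrate_g + 1e-9:
            raise ValueError(f"{self.item_id}: sucrose exceeds carbohydrate")
        if self.saturated_fat_g > self.fat_g + 1e-9:
            raise ValueError(f"{self.item_id}: saturated fat exceeds total fat")


class CompositionTable:
    """Lookup of :class:`CompositionEntry` by item id."""

    def __init__(self, entries: Iterable[CompositionEntry]):
        self._entries = {e.item_id: e for e in entries}

    def __getitem__(self, item_id: str) -> CompositionEntry:
        try:
            return self._entries[item_id]
        except KeyError:
            raise KeyError(
                f"no composition entry for item {item_id!r}; "
                "the composition table must cover every questionnaire item"
            ) from None

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)


def load_composition(source: str | Path | None = None) -> CompositionTable:
    """Load a composition table from CSV (packaged fixture when ``source`` is
    None).

    The packaged densities are plausible fixture values for a Nordic diet,
    documented in the repository; they are not a transcription of any
    national food-composition database.
    """
    if source is None:
        with resources.files("fiq16.data").joinpath("composition.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(source)
    required = {"item_id", "portion_g", *_DENSITY_FIELDS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"composition table missing columns: {sorted(missing)}")
    entries = [
        CompositionEntry(
            item_id=str(row.item_id),
            portion_g=float(row.portion_g),
            **{f: float(getattr(row, f)) for f in _DENSITY_FIELDS},
        )
        for row in df.itertuples(index=False)
    ]
    return CompositionTable(entries)


# ---------------------------------------------------------------------------
# Canonical numeric encodings

#: Names of the numeric scoring features produced by :func:`encode_features`,
#: in questionnaire order.  These are the item values the sum-score models
#: weight with integer multipliers; counts keep the units the questionnaire
#: asks them in (dishes per week, slices per day, ...).
SCORE_FEATURES = (
    "meals_per_day",
    "fastfood_per_day",
    "fruit_portions_per_day",
    "vegetable_portions_per_day",
    "sugar_rich_per_day",
    "sweets_per_day",
    "butter_in_cooking",
    "cream_in_cooking",
    "butter_on_bread",
    "margarine_on_bread",
    "oil_dressing",
    "fish_dishes_per_week",
    "sausage_dishes_per_week",
    "chicken_dishes_per_week",
    "meat_dishes_per_week",
    "vegetable_dishes_per_week",
    "milk_dl_per_day",
    "cheese_slices_per_day",
    "coldcut_slices_per_day",
    "frankfurters_per_day",
    "rye_bread_slices_per_day",
    "multigrain_bread_slices_per_day",
    "white_bread_slices_per_day",
    "porridge_dl_per_day",
    "cereal_dl_per_day",
    "tea_per_day",
    "coffee_per_day",
    "soft_drinks_per_day",
    "sugar_sweetened_juices_per_day",
    "fruit_juices_per_day",
    "beer_per_day",
    "wine_per_day",
    "spirits_per_day",
    "male",
)


def encode_features(response: QuestionnaireResponse, codebook: Codebook) -> dict[str, float]:
    """Encode a response as the canonical numeric feature vector used by the
    scoring models.

    Ordinal answers become codebook midpoints (per day); type answers become
    0/1 indicators; open-ended counts keep their questionnaire units (e.g.
    sausage dishes *per week*, cheese slices *per day*), matching the
    arithmetic of the published worked example; sex becomes a male indicator.
    """
    response.validate_against(codebook)
    r = response
    feats = {
        "meals_per_day": codebook.daily_rate("meals_per_day", r.meals_per_day),
        "fastfood_per_day": codebook.daily_rate("fastfood", r.freq_fastfood),
        "fruit_portions_per_day": codebook.daily_rate("fruit", r.freq_fruit),
        "vegetable_portions_per_day": codebook.daily_rate("vegetable", r.freq_vegetable),
        "sugar_rich_per_day": codebook.daily_rate("sugar_rich", r.freq_sugar_rich),
        "sweets_per_day": codebook.daily_rate("sweets", r.freq_sweets),
        "butter_in_cooking": float(r.cooking_fat_type == "butter_or_butter_spread"),
        "cream_in_cooking": float(r.cream_in_cooking == "yes"),
        "butter_on_bread": float(r.spread_on_bread_type == "butter_or_butter_spread"),
        "margarine_on_bread": float(r.spread_on_bread_type == "vegetable_margarine"),
        "oil_dressing": float(r.dressing_type == "oil_based"),
        "fish_dishes_per_week": r.dishes_per_week["fish"],
        "sausage_dishes_per_week": r.dishes_per_week["sausage"],
        "chicken_dishes_per_week": r.dishes_per_week["chicken"],
        "meat_dishes_per_week": r.dishes_per_week["meat"],
        "vegetable_dishes_per_week": r.dishes_per_week["vegetable"],
        "milk_dl_per_day": sum(r.milk_dl_per_day.values()),
        "cheese_slices_per_day": sum(r.cheese_slices_per_day.values()),
        "coldcut_slices_per_day": (
            r.coldcut_slices_per_day["low_fat"] + r.coldcut_slices_per_day["regular"]
        ),
        "frankfurters_per_day": r.coldcut_slices_per_day["frankfurter"],
        "rye_bread_slices_per_day": r.bread_slices_per_day["rye_crisp"],
        "multigrain_bread_slices_per_day": r.bread_slices_per_day["multigrain"],
        "white_bread_slices_per_day": r.bread_slices_per_day["white"],
        "porridge_dl_per_day": r.cereal_dl_per_day["porridge"],
        "cereal_dl_per_day": r.cereal_dl_per_day["other"],
        "tea_per_day": r.beverages_per_day["tea"],
        "coffee_per_day": r.beverages_per_day["coffee"],
        "soft_drinks_per_day": r.beverages_per_day["soft_drink"],
        "sugar_sweetened_juices_per_day": r.beverages_per_day["sugar_sweetened_juice"],
        "fruit_juices_per_day": r.beverages_per_day["fruit_juice"],
        "beer_per_day": r.beverages_per_day["beer"],
        "wine_per_day": r.beverages_per_day["wine"],
        "spirits_per_day": r.beverages_per_day["spirits"],
        "male": float(r.sex == "male"),
    }
    assert tuple(feats) == SCORE_FEATURES
    return feats


def questionnaire_frequencies(
    response: QuestionnaireResponse, codebook: Codebook
) -> dict[str, float]:
    """Per-day questionnaire consumption frequency for each of the 26
    food-record food groups.

    Used on the questionnaire side of the food-group comparison: food-record
    grams per day versus questionnaire frequency per day.
    """
    f = encode_features(response, codebook)
    return {
        "fish_dishes": f["fish_dishes_per_week"] / 7,
        "sausage_dishes": f["sausage_dishes_per_week"] / 7,
        "poultry_dishes": f["chicken_dishes_per_week"] / 7,
        "meat_dishes": f["meat_dishes_per_week"] / 7,
        "vegetable_dishes": f["vegetable_dishes_per_week"] / 7,
        "fast_foods": f["fastfood_per_day"],
        "vegetables": f["vegetable_portions_per_day"],
        "fruits_and_berries": f["fruit_portions_per_day"],
        "milk_products": f["milk_dl_per_day"],
        "rye_breads": f["rye_bread_slices_per_day"],
        "multigrain_breads": f["multigrain_bread_slices_per_day"],
        "white_breads": f["white_bread_slices_per_day"],
        "porridges": f["porridge_dl_per_day"],
        "breakfast_cereals": f["cereal_dl_per_day"],
        "cheeses": f["cheese_slices_per_day"],
        "cold_cuts": f["coldcut_slices_per_day"] + f["frankfurters_per_day"],
        "desserts": f["sugar_rich_per_day"],
        "sweets_and_sugar": f["sweets_per_day"],
        "tea": f["tea_per_day"],
        "coffee": f["coffee_per_day"],
        "soft_drinks": f["soft_drinks_per_day"],
        "sugar_sweetened_juices": f["sugar_sweetened_juices_per_day"],
        "fruit_juices": f["fruit_juices_per_day"],
        "beer": f["beer_per_day"],
        "wine": f["wine_per_day"],
        "distilled_spirits": f["spirits_per_day"],
    }


# ---------------------------------------------------------------------------
# Tabular I/O for responses

_SCALAR_COLUMNS = (
    ("participant_id", "participant_id"),
    ("sex", "sex"),
    ("meals_per_day", "meals_per_day"),
    ("freq_fastfood", "fastfood"),
    ("freq_fruit", "fruit"),
    ("freq_vegetable", "vegetable"),
    ("freq_sugar_rich", "sugar_rich"),
    ("freq_sweets", "sweets"),
    ("cooking_fat_type", "cooking_fat"),
    ("cream_in_cooking", "cream_in_cooking"),
    ("spread_on_bread_type", "spread"),
    ("dressing_type", "dressing"),
)

_DICT_COLUMNS = (
    ("dishes_per_week", "dishes", DISH_GROUPS),
    ("milk_dl_per_day", "milk", MILK_CLASSES),
    ("cheese_slices_per_day", "cheese", CHEESE_CLASSES),
    ("coldcut_slices_per_day", "coldcut", COLDCUT_CLASSES),
    ("bread_slices_per_day", "bread", BREAD_CLASSES),
    ("cereal_dl_per_day", "cereal", CEREAL_CLASSES),
    ("beverages_per_day", "bev", BEVERAGE_CLASSES),
)


def response_columns() -> list[str]:
    cols = [col for _, col in _SCALAR_COLUMNS]
    for _, prefix, keys in _DICT_COLUMNS:
        cols.extend(f"{prefix}_{k}" for k in keys)
    return cols


def write_responses(
    responses: Iterable[QuestionnaireResponse], path: str | Path, sep: str = ","
) -> None:
    """Write responses as a delimited table, one participant per row."""
    rows = []
    for r in responses:
        row: dict[str, object] = {col: getattr(r, attr) for attr, col in _SCALAR_COLUMNS}
        for attr, prefix, keys in _DICT_COLUMNS:
            d = getattr(r, attr)
            for k in keys:
                row[f"{prefix}_{k}"] = d[k]
        rows.append(row)
    pd.DataFrame(rows, columns=response_columns()).to_csv(path, index=False, sep=sep)


def read_responses(path: str | Path, sep: str = ",") -> list[QuestionnaireResponse]:
    """Read responses from a delimited table written by :func:`write_responses`.

    Any missing column or empty cell is an error: the pipeline treats an
    incomplete questionnaire as invalid rather than imputing.
    """
    df = pd.read_csv(path, sep=sep, dtype={"participant_id": str})
    missing = set(response_columns()) - set(df.columns)
    if missing:
        raise ResponseError(f"{path}: missing columns {sorted(missing)}")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise ResponseError(f"{path}: missing values in columns {bad}")
    out = []
    for row in df.to_dict("records"):
        kwargs: dict[str, object] = {attr: row[col] for attr, col in _SCALAR_COLUMNS}
        for attr, prefix, keys in _DICT_COLUMNS:
            kwargs[attr] = {k: float(row[f"{prefix}_{k}"]) for k in keys}
        out.append(QuestionnaireResponse(**kwargs))  # type: ignore[arg-type]
    return out


# ---------------------------------------------------------------------------
# Food-record summaries


@dataclass
class FoodRecordSummary:
    """Per-participant 7-day food-record summary: mean daily grams for the 26
    food groups and the 12 nutrient variables (reference method)."""

    participant_id: str
    food_group_g_per_day: dict[str, float]
    nutrients: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.food_group_g_per_day) != set(FOOD_GROUPS):
            raise ResponseError(
                f"food record {self.participant_id}: food groups must be exactly "
                f"the {len(FOOD_GROUPS)} reference groups"
            )
        if set(self.nutrients) != set(NUTRIENTS):
            raise ResponseError(
                f"food record {self.participant_id}: nutrient keys must be exactly "
                f"the {len(NUTRIENTS)} reference nutrients"
            )
        for d in (self.food_group_g_per_day, self.nutrients):
            for k, v in d.items():
                if not (math.isfinite(v) and v >= 0):
                    raise ResponseError(
                        f"food record {self.participant_id}: {k} must be finite and >= 0"
                    )


def write_food_records(
    records: Iterable[FoodRecordSummary], path: str | Path, sep: str = ","
) -> None:
    rows = []
    for rec in records:
        row: dict[str, object] = {"participant_id": rec.participant_id}
        row.update({f"fg_{g}": rec.food_group_g_per_day[g] for g in FOOD_GROUPS})
        row.update({f"nu_{n}": rec.nutrients[n] for n in NUTRIENTS})
        rows.append(row)
    cols = ["participant_id"] + [f"fg_{g}" for g in FOOD_GROUPS] + [f"nu_{n}" for n in NUTRIENTS]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, sep=sep)


def read_food_records(path: str | Path, sep: str = ",") -> list[FoodRecordSummary]:
    df = pd.read_csv(path, sep=sep, dtype={"participant_id": str})
    need = {"participant_id"} | {f"fg_{g}" for g in FOOD_GROUPS} | {f"nu_{n}" for n in NUTRIENTS}
    missing = need - set(df.columns)
    if missing:
        raise ResponseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.to_dict("records"):
        out.append(
            FoodRecordSummary(
                participant_id=str(row["participant_id"]),
                food_group_g_per_day={g: float(row[f"fg_{g}"]) for g in FOOD_GROUPS},
                nutrients={n: float(row[f"nu_{n}"]) for n in NUTRIENTS},
            )
        )
    return out
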