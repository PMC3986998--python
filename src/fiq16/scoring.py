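"""Apply scoring models to questionnaire responses.

This is the patient-facing end of the pipeline: given a fitted
:class:`~fiq16.models.ScoringModel` (or the published fat model shipped as a
fixture), compute each participant's sum score and estimated nutrient
intake.  Predictions below zero are clamped to zero with a logged warning
(intakes cannot be negative); values are kept at full precision internally
and rounded to one decimal only for display.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .core import Codebook, QuestionnaireResponse, encode_features
from .models import ScoringModel

logger = logging.getLogger(__name__)

__all__ = ["published_fat_model", "score_response", "score_cohort", "example_fat_response"]


def published_fat_model() -> ScoringModel:
    """The published fat-intake (E%) scoring model, shipped as a fixture.

    Only the fat model's constants are printed in the retrieved source; the
    remaining six nutrient models must be refit (``fit_scoring_model``) or
    supplied by the user.  See the fixture file for the one synthetic
    stand-in (the butter-in-cooking multiplier).
    """
    with resources.as_file(
        resources.files("fiq16.data").joinpath("fat_model_published.yaml")
    ) as p:
        return ScoringModel.from_yaml(p)


def example_fat_response(codebook: Codebook | None = None) -> QuestionnaireResponse:
    """The worked-example male participant: 2 sausage dishes/week, no butter
    in cooking, 1 fruit portion/day, 6 cheese slices/day, no frankfurters.

    Items the example leaves unstated are set to zero/none so they cannot
    contribute to the fat sum score.
    """
    return QuestionnaireResponse(
        participant_id="example",
        sex="male",
        meals_per_day="3-4",
        freq_fastfood="less_than_once_a_month",
        freq_fruit="1_per_day",
        freq_vegetable="1_per_day",
        freq_sugar_rich="less_than_once_a_month",
        freq_sweets="less_than_once_a_month",
        cooking_fat_type="vegetable_oil_or_margarine",
        cream_in_cooking="no",
        spread_on_bread_type="none",
        dressing_type="none",
        dishes_per_week={"fish": 0, "sausage": 2, "chicken": 0, "meat": 0, "vegetable": 0},
        milk_dl_per_day={"skimmed": 0, "semi_skimmed": 0, "whole": 0},
        cheese_slices_per_day={"low_fat": 0, "regular": 6},
        coldcut_slices_per_day={"low_fat": 0, "regular": 0, "frankfurter": 0},
        bread_slices_per_day={"rye_crisp": 0, "multigrain": 0, "white": 0},
        cereal_dl_per_day={"porridge": 0, "other": 0},
        beverages_per_day={k: 0 for k in (
            "tea", "coffee", "soft_drink", "sugar_sweetened_juice",
            "fruit_juice", "beer", "wine", "spirits")},
    )


def score_response(
    model: ScoringModel, response: QuestionnaireResponse, codebook: Codebook
) -> float:
    """Estimated intake for one participant under one scoring model.

    Raises ``KeyError`` naming the item if the response encoding lacks a
    scored item; clamps negative predictions to 0 with a warning.
    """
    features = encode_features(response, codebook)
    pred = model.predict_from_features(features)
    if pred < 0:
        logger.warning(
            "participant %s: %s prediction %.3f clamped to 0",
            response.participant_id, model.nutrient_id, pred,
        )
        return 0.0
    return pred


def score_cohort(
    models: Mapping[str, ScoringModel],
    responses: Iterable[QuestionnaireResponse],
    codebook: Codebook,
) -> pd.DataFrame:
    """Apply every model to every response: one row per participant, one
    column per nutrient, plus a ``flag`` column listing scoring errors.

    A failing response is flagged but does not stop the rest of the cohort.
    """
    rows = []
    for r in responses:
        row: dict[str, object] = {"participant_id": r.participant_id}
        errors = []
        for name, model in models.items():
            try:
                row[name] = score_response(model, r, codebook)
            except Exception as exc:  # error isolation per participant
                row[name] = float("nan")
                errors.append(f"{name}: {exc}")
        row["flag"] = "; ".join(errors)
        rows.append(row)
    cols = ["participant_id", *models.keys(), "flag"]
    return pd.DataFrame(rows, columns=cols)


def write_scores(scores: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a cohort score table, nutrient values rounded to one decimal
    for display (full precision stays with the in-memory frame)."""
    out = scores.copy()
    for c in out.columns:
        if c not in ("participant_id", "flag"):
            out[c] = out[c].round(1)
    out.to_csv(path, index=False, sep=sep)
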