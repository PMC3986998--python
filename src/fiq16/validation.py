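"""Agreement statistics between questionnaire and food-record intakes.

The comparison mirrors standard short-questionnaire validation practice:

* Spearman rank correlation per food group (questionnaire frequency per day
  versus food-record grams per day) and per nutrient (questionnaire-estimated
  versus food-record intake), two-sided p from the t approximation,
  significance flagged at alpha = 0.05;
* rank-based tertile split of the cohort by each instrument, with exact
  (same tertile) and opposite (extreme-to-extreme misclassification)
  agreement percentages from the 3x3 cross-classification;
* weighted kappa on the cross-classification, chance-corrected with
  distance-based disagreement weights (linear by default, quadratic
  available; the report records which was used).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    FOOD_GROUPS,
    NUTRIENTS,
    Codebook,
    CompositionTable,
    FoodRecordSummary,
    QuestionnaireResponse,
    questionnaire_frequencies,
)
from .estimation import EstimationConfig, estimate_nutrients

logger = logging.getLogger(__name__)

__all__ = [
    "ConstantInputError",
    "AgreementResult",
    "ValidationReport",
    "spearman",
    "assign_tertiles",
    "cross_classification",
    "weighted_kappa",
    "validate",
]

ALPHA = 0.05


class ConstantInputError(ValueError):
    """Rank correlation is undefined when one vector is constant."""


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns ``(r_s, p)`` with a two-sided p-value from the t-distribution
    approximation.  Raises :class:`ConstantInputError` for a constant
    vector, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("constant vector: rank correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def assign_tertiles(values: Sequence[float]) -> np.ndarray:
    """Rank-based tertile labels in {1, 2, 3}.

    Group sizes differ by at most one, with the larger groups at the lower
    end (n = 77 gives 26/26/25).  Ties are broken by original position
    (stable sort), so participants sharing a boundary value are assigned
    deterministically, lowest tertile first; an all-constant vector is
    split the same way, with a logged warning.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 observations to form tertiles")
    if np.ptp(values) == 0:
        logger.warning("assign_tertiles: constant vector, labels assigned by position")
    order = np.argsort(values, kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    labels = np.empty(n, dtype=int)
    start = 0
    for tertile, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = tertile
        start += size
    return labels


def cross_classification(
    labels_a: Sequence[int], labels_b: Sequence[int]
) -> tuple[np.ndarray, float, float]:
    """3x3 cross table plus exact and opposite agreement percentages.

    Exact agreement: share of participants in the same tertile under both
    instruments (diagonal).  Opposite agreement: share classified into
    opposite extremes (cells (1,3) and (3,1)).
    """
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("label vectors must be one-dimensional, non-empty, equal length")
    if not (np.isin(a, (1, 2, 3)).all() and np.isin(b, (1, 2, 3)).all()):
        raise ValueError("tertile labels must be in {1, 2, 3}")
    table = np.zeros((3, 3), dtype=int)
    np.add.at(table, (a - 1, b - 1), 1)
    n = a.size
    exact_pct = 100.0 * np.trace(table) / n
    opposite_pct = 100.0 * (table[0, 2] + table[2, 0]) / n
    return table, exact_pct, opposite_pct


def weighted_kappa(cross_table: np.ndarray, scheme: str = "linear") -> float:
    """Weighted kappa for a k x k ordered-category agreement table.

    kappa_w = 1 - sum(w * observed) / sum(w * expected), with expected
    counts from the row/column marginals and disagreement weights
    w_ij = |i-j|/(k-1) (linear) or ((i-j)/(k-1))^2 (quadratic).  Perfect
    agreement gives 1; agreement at chance level gives 0.
    """
    table = np.asarray(cross_table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("cross table must be square")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    n = table.sum()
    if n <= 0:
        raise ValueError("empty cross table")
    k = table.shape[0]
    if scheme not in ("linear", "quadratic"):
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    idx = np.arange(k)
    dist = np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    w = dist if scheme == "linear" else dist**2
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    denom = (w * expected).sum()
    num = (w * table).sum()
    if denom == 0:
        # all marginal mass in one category: perfect if observed agrees
        return 1.0 if num == 0 else float("nan")
    return float(1.0 - num / denom)


@dataclass
class AgreementResult:
    """Agreement statistics for one food group or nutrient."""

    variable: str
    r_s: float
    p_value: float
    significant: bool
    exact_pct: float | None = None
    opposite_pct: float | None = None
    weighted_kappa: float | None = None
    cross_table: list | None = None

    def as_row(self) -> dict:
        return {
            "variable": self.variable,
            "r_s": self.r_s,
            "p_value": self.p_value,
            "significant": self.significant,
            "exact_pct": self.exact_pct,
            "opposite_pct": self.opposite_pct,
            "weighted_kappa": self.weighted_kappa,
        }


@dataclass
class ValidationReport:
    """Food-group and nutrient agreement between the two instruments."""

    n: int
    kappa_scheme: str
    food_groups: dict[str, AgreementResult] = field(default_factory=dict)
    nutrients: dict[str, AgreementResult] = field(default_factory=dict)

    def food_group_frame(self) -> pd.DataFrame:
        rows = [self.food_groups[g].as_row() for g in FOOD_GROUPS if g in self.food_groups]
        return pd.DataFrame(rows)[["variable", "r_s", "p_value", "significant"]]

    def nutrient_frame(self) -> pd.DataFrame:
        rows = [self.nutrients[v].as_row() for v in NUTRIENTS if v in self.nutrients]
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path, sep: str = ",") -> None:
        """Write the two delimited tables plus a machine-readable JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.food_group_frame().to_csv(outdir / "food_group_agreement.csv", index=False, sep=sep)
        self.nutrient_frame().to_csv(outdir / "nutrient_agreement.csv", index=False, sep=sep)
        payload = {
            "n": self.n,
            "kappa_scheme": self.kappa_scheme,
            "food_groups": {
                g: {**r.as_row(), "cross_table": r.cross_table}
                for g, r in self.food_groups.items()
            },
            "nutrients": {
                v: {**r.as_row(), "cross_table": r.cross_table}
                for v, r in self.nutrients.items()
            },
        }
        (outdir / "validation_report.json").write_text(json.dumps(payload, indent=2))


def validate(
    responses: Iterable[QuestionnaireResponse],
    records: Iterable[FoodRecordSummary],
    codebook: Codebook,
    composition: CompositionTable,
    config: EstimationConfig | None = None,
    kappa_scheme: str = "linear",
) -> ValidationReport:
    """Full two-instrument comparison for a paired cohort.

    Participants are matched by id; an unmatched participant on either side
    is an error.  Food groups get Spearman only (frequency vs grams);
    nutrients additionally get tertile cross-classification, exact/opposite
    agreement and weighted kappa.  Zero-energy questionnaire responses are
    excluded from the nutrient comparison with a logged warning.
    """
    responses = list(responses)
    records = list(records)
    resp_ids = {r.participant_id for r in responses}
    rec_ids = {r.participant_id for r in records}
    if resp_ids != rec_ids:
        only_resp = sorted(resp_ids - rec_ids)
        only_rec = sorted(rec_ids - resp_ids)
        raise ValueError(
            f"unmatched participants: questionnaire-only {only_resp}, record-only {only_rec}"
        )
    order = [r.participant_id for r in responses]
    rec_by_id = {r.participant_id: r for r in records}
    records = [rec_by_id[pid] for pid in order]

    report = ValidationReport(n=len(responses), kappa_scheme=kappa_scheme)

    # Food groups: questionnaire frequency/day vs record g/day.
    freq_rows = [questionnaire_frequencies(r, codebook) for r in responses]
    for g in FOOD_GROUPS:
        x = [row[g] for row in freq_rows]
        y = [rec.food_group_g_per_day[g] for rec in records]
        try:
            r_s, p = spearman(x, y)
        except ConstantInputError:
            logger.warning("food group %s: constant vector, correlation skipped", g)
            continue
        report.food_groups[g] = AgreementResult(g, r_s, p, p < ALPHA)

    # Nutrients: estimated vs record intake, with tertile agreement.
    intakes = [estimate_nutrients(r, codebook, composition, config) for r in responses]
    keep = [i for i, it in enumerate(intakes) if it.has_energy]
    if len(keep) < len(intakes):
        dropped = [responses[i].participant_id for i in range(len(intakes)) if i not in keep]
        logger.warning("excluding zero-energy responses from nutrient comparison: %s", dropped)
    est_rows = [intakes[i].as_nutrient_row() for i in keep]
    rec_rows = [records[i].nutrients for i in keep]
    for v in NUTRIENTS:
        x = [row[v] for row in est_rows]
        y = [row[v] for row in rec_rows]
        try:
            r_s, p = spearman(x, y)
        except (ConstantInputError, ValueError) as exc:
            logger.warning("nutrient %s: %s; skipped", v, exc)
            continue
        tert_x = assign_tertiles(x)
        tert_y = assign_tertiles(y)
        table, exact_pct, opposite_pct = cross_classification(tert_x, tert_y)
        kappa = weighted_kappa(table, kappa_scheme)
        report.nutrients[v] = AgreementResult(
            v,
            r_s,
            p,
            p < ALPHA,
            exact_pct=exact_pct,
            opposite_pct=opposite_pct,
            weighted_kappa=kappa,
            cross_table=table.tolist(),
        )
    return report
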