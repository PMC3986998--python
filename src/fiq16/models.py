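"""Scoring-model builder: integer-multiplier sum scores fit by coordinate
hill climbing on R-squared.

A scoring model predicts a nutrient intake from a handful of questionnaire
answers with pencil-and-paper arithmetic: each included item value x_i is
weighted with a small integer multiplier m_i, the weighted values are summed
into a sum score SC = sum(m_i * x_i), and the intake is read off a simple
linear regression of the food-record reference intake on SC,

    intake = intercept + slope * SC                       (linear target)
    intake = exp(MSE/2) * exp(intercept + slope * SC)     (log target)

The multiplicative exp(MSE/2) factor corrects the downward bias introduced
by back-transforming predictions from a natural-log-scale regression.

The multipliers are found by a deterministic coordinate search: items are
visited in a fixed order; for the current item the multiplier is stepped by
+1 (then -1) as long as the R-squared of the regression on the resulting sum
score strictly increases; passes over the items repeat until a full pass
changes nothing.  The returned configuration is locally optimal: no single
+-1 change to any multiplier increases R-squared.  Because only the product
slope * m_i is identifiable, multipliers are conventions as much as
estimates -- rescaling all multipliers and the slope inversely leaves
predictions unchanged.

The search is exposed as a scikit-learn regressor
(:class:`IntegerScoreRegressor`) so it composes with sklearn model
selection; :func:`optimize_multipliers` and :func:`fit_scoring_model` are
thin wrappers over it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DegenerateFitError",
    "NonConvergenceError",
    "ScoringModel",
    "FitDataset",
    "IntegerScoreRegressor",
    "build_sum_score",
    "fit_linear",
    "optimize_multipliers",
    "bias_correction_factor",
    "fit_scoring_model",
    "residual_diagnostics",
]


class DegenerateFitError(ValueError):
    """Raised when the regression is degenerate (constant scores)."""


class NonConvergenceError(RuntimeError):
    """Raised when the multiplier search exceeds its safety caps."""


def build_sum_score(
    item_values: Mapping[str, float], multipliers: Mapping[str, int]
) -> float:
    """Integer-weighted sum score SC = sum(multiplier_i * value_i).

    Every item with a nonzero multiplier must have a value; zero-multiplier
    items may be absent.
    """
    sc = 0.0
    for item, m in multipliers.items():
        if item not in item_values:
            if m == 0:
                continue
            raise KeyError(f"missing value for scored item {item!r}")
        sc += m * item_values[item]
    return sc


def fit_linear(
    scores: Sequence[float], targets: Sequence[float], log_flag: bool = False
) -> tuple[float, float, float, float]:
    """Ordinary least squares of the (optionally log-transformed) target on
    the sum score.

    Returns ``(intercept, slope, r_squared, mse)`` where ``mse`` is the
    regression mean squared error SSE/(n-2), the residual-variance estimate
    that enters the exp(MSE/2) back-transformation correction.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(targets, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("scores and targets must be one-dimensional, equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if log_flag:
        if (y <= 0).any():
            raise ValueError("log transform requires strictly positive targets")
        y = np.log(y)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise DegenerateFitError("constant scores: slope is not identifiable")
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    syy = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if syy == 0 else 1.0 - sse / syy
    mse = sse / (n - 2)
    return float(intercept), float(slope), float(r_squared), float(mse)


def bias_correction_factor(mse: float) -> float:
    """Multiplicative back-transformation correction exp(MSE/2)."""
    if mse < 0:
        raise ValueError("mse must be >= 0")
    return math.exp(mse / 2.0)


def _r2_for_multipliers(
    X: np.ndarray, y: np.ndarray, m: np.ndarray, sex: np.ndarray | None
) -> float:
    """R-squared of y on the sum score X @ m (plus an optional separate sex
    covariate).  Returns -inf for a degenerate (constant) score."""
    score = X @ m
    if sex is None:
        sxx = np.sum((score - score.mean()) ** 2)
        if sxx == 0:
            return -np.inf
        sxy = np.sum((score - score.mean()) * (y - y.mean()))
        syy = np.sum((y - y.mean()) ** 2)
        if syy == 0:
            return 1.0
        return float(sxy * sxy / (sxx * syy))
    design = np.column_stack([np.ones_like(score), score, sex])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        return -np.inf
    resid = y - design @ coef
    syy = np.sum((y - y.mean()) ** 2)
    if syy == 0:
        return 1.0
    return float(1.0 - np.sum(resid**2) / syy)


class IntegerScoreRegressor(RegressorMixin, BaseEstimator):
    """Simple linear regression on an integer-weighted sum of item values,
    with the integer weights found by +-1 coordinate hill climbing on
    R-squared.

    Parameters
    ----------
    init_multiplier : int, default 1
        Starting value for every free multiplier.
    log_target : bool, default False
        Regress the natural log of the target and apply the exp(MSE/2)
        back-transformation correction when predicting.
    max_multiplier : int, default 100
        Safety cap on |multiplier|; exceeding it raises
        :class:`NonConvergenceError`.
    max_passes : int, default 500
        Safety cap on full passes over the items.
    item_order : sequence of str or int, optional
        Order in which items are visited within a pass; defaults to column
        order.
    sex_covariate : str or None, default None
        Name (or index) of a column to model as a separate regression
        covariate instead of a scored item.  By default sex is treated like
        any other item: an indicator column with an integer multiplier, the
        arithmetic the published worked example uses.
    exhaust_items : bool, default False
        If True, keep stepping the current item while R-squared strictly
        increases before moving on.  The default takes at most one +-1 step
        per item per pass, letting the multipliers co-evolve.  Both variants
        accept only strict improvements and stop at a +-1-local optimum;
        the one-step default exists because exhausting an item can ride a
        monotone R-squared ridge (diluting not-yet-adjusted items) all the
        way to the multiplier cap.

    Attributes
    ----------
    multipliers_ : ndarray of int, shape (n_items,)
    intercept_, slope_ : float
    r_squared_, mse_ : float
    bias_factor_ : float  (exp(mse/2) when log_target, else 1.0)
    r2_history_ : list of float  (R-squared after every accepted step;
        nondecreasing)
    n_passes_ : int
    feature_names_in_ : ndarray of str (when fit on a DataFrame)
    """

    def __init__(
        self,
        init_multiplier: int = 1,
        log_target: bool = False,
        max_multiplier: int = 100,
        max_passes: int = 500,
        item_order: Sequence | None = None,
        sex_covariate: str | int | None = None,
        exhaust_items: bool = False,
    ):
        self.init_multiplier = init_multiplier
        self.log_target = log_target
        self.max_multiplier = max_multiplier
        self.max_passes = max_passes
        self.item_order = item_order
        self.sex_covariate = sex_covariate
        self.exhaust_items = exhaust_items

    # -- internal helpers ---------------------------------------------------

    def _resolve_columns(self, X) -> tuple[np.ndarray, np.ndarray | None, list]:
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise ValueError("X must be two-dimensional")
            names = list(range(arr.shape[1]))
        sex = None
        if self.sex_covariate is not None:
            if self.sex_covariate not in names:
                raise ValueError(f"sex covariate {self.sex_covariate!r} not among columns")
            j = names.index(self.sex_covariate)
            sex = arr[:, j]
            arr = np.delete(arr, j, axis=1)
            names = [c for c in names if c != self.sex_covariate]
        return arr, sex, names

    def fit(self, X, y):
        """Run the coordinate search and the final regression.

        X holds one column per scored item (numeric answers in questionnaire
        units); y is the food-record reference intake.
        """
        arr, sex, names = self._resolve_columns(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or y.size != arr.shape[0]:
            raise ValueError("y must be one-dimensional and match X")
        n, k = arr.shape
        if n < 4:
            raise ValueError("need at least 4 observations")
        y_work = y
        if self.log_target:
            if (y <= 0).any():
                raise ValueError("log transform requires strictly positive targets")
            y_work = np.log(y)

        order = list(self.item_order) if self.item_order is not None else list(names)
        if sorted(map(str, order)) != sorted(map(str, names)):
            raise ValueError("item_order must be a permutation of the item columns")
        order_idx = [names.index(c) if c in names else int(c) for c in order]

        m = np.full(k, int(self.init_multiplier), dtype=int)
        r2 = _r2_for_multipliers(arr, y_work, m, sex)
        history = [r2]
        n_passes = 0
        while True:
            if n_passes >= self.max_passes:
                raise NonConvergenceError(
                    f"multiplier search did not settle within {self.max_passes} passes"
                )
            n_passes += 1
            changed = False
            for j in order_idx:
                for step in (1, -1):
                    stepped = False
                    while True:
                        if abs(m[j] + step) > self.max_multiplier:
                            raise NonConvergenceError(
                                f"multiplier for item {names[j]!r} exceeded "
                                f"|{self.max_multiplier}|"
                            )
                        m[j] += step
                        new_r2 = _r2_for_multipliers(arr, y_work, m, sex)
                        if new_r2 > r2:
                            r2 = new_r2
                            history.append(r2)
                            changed = True
                            stepped = True
                            if not self.exhaust_items:
                                break
                        else:
                            m[j] -= step
                            break
                    if stepped:
                        break  # improving direction found; skip the other
            if not changed:
                break

        score = arr @ m
        if sex is None:
            intercept, slope, r_squared, mse = fit_linear(score, y, self.log_target)
            self.sex_coef_ = None
        else:
            design = np.column_stack([np.ones(n), score, sex])
            coef, _, _, _ = np.linalg.lstsq(design, y_work, rcond=None)
            resid = y_work - design @ coef
            sse = float(np.sum(resid**2))
            syy = float(np.sum((y_work - y_work.mean()) ** 2))
            intercept, slope = float(coef[0]), float(coef[1])
            self.sex_coef_ = float(coef[2])
            r_squared = 1.0 if syy == 0 else 1.0 - sse / syy
            mse = sse / (n - 3)

        self.multipliers_ = m
        self.intercept_ = intercept
        self.slope_ = slope
        self.r_squared_ = float(r_squared)
        self.mse_ = float(mse)
        self.bias_factor_ = bias_correction_factor(mse) if self.log_target else 1.0
        self.r2_history_ = history
        self.n_passes_ = n_passes
        self.n_features_in_ = k + (1 if sex is not None else 0)
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self._fit_names = names
        return self

    def predict(self, X):
        check_is_fitted(self, "multipliers_")
        arr, sex, names = self._resolve_columns(X)
        if names != self._fit_names:
            # positional use is fine as long as shapes agree
            if arr.shape[1] != len(self._fit_names):
                raise ValueError("X has a different number of item columns than at fit")
        score = arr @ self.multipliers_
        linpred = self.intercept_ + self.slope_ * score
        if sex is not None and self.sex_coef_ is not None:
            linpred = linpred + self.sex_coef_ * sex
        if self.log_target:
            return self.bias_factor_ * np.exp(linpred)
        return linpred

    def is_local_optimum(self, X, y) -> bool:
        """Exhaustively check that no single +-1 multiplier change increases
        R-squared (the search's termination contract)."""
        check_is_fitted(self, "multipliers_")
        arr, sex, _ = self._resolve_columns(X)
        y_work = np.asarray(y, dtype=float)
        if self.log_target:
            y_work = np.log(y_work)
        base = _r2_for_multipliers(arr, y_work, self.multipliers_, sex)
        for j in range(self.multipliers_.size):
            for step in (1, -1):
                trial = self.multipliers_.copy()
                trial[j] += step
                if _r2_for_multipliers(arr, y_work, trial, sex) > base + 1e-12:
                    return False
        return True


# ---------------------------------------------------------------------------
# Dataclasses and functional wrappers


@dataclass
class FitDataset:
    """Per-participant item values and the food-record reference intake for
    one nutrient."""

    X: pd.DataFrame
    y: pd.Series
    nutrient_id: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have the same length")
        if self.X.isna().any().any() or self.y.isna().any():
            raise ValueError("FitDataset does not allow missing values")
        if len(self.X) < self.X.shape[1] + 2:
            raise ValueError("too few participants for the number of scored items")


@dataclass
class ScoringModel:
    """A fitted (or published) per-nutrient scoring model.

    Holds everything needed to reproduce predictions exactly: integer item
    multipliers, intercept, slope, the log-transform flag and its
    exp(MSE/2) bias factor, plus fit statistics.
    """

    nutrient_id: str
    unit: str
    multipliers: dict[str, int]
    intercept: float
    slope: float
    log_flag: bool = False
    bias_factor: float = 1.0
    r_squared: float = float("nan")
    mse: float = float("nan")
    notes: str = ""

    def __post_init__(self) -> None:
        for item, m in self.multipliers.items():
            if int(m) != m:
                raise ValueError(f"multiplier for {item!r} must be an integer, got {m}")
            self.multipliers[item] = int(m)
        if self.log_flag and self.bias_factor < 1.0:
            raise ValueError("bias factor exp(MSE/2) must be >= 1 for a log model")
        if not self.log_flag and self.bias_factor != 1.0:
            raise ValueError("bias factor must be 1 for a non-log model")

    def sum_score(self, item_values: Mapping[str, float]) -> float:
        return build_sum_score(item_values, self.multipliers)

    def predict_from_features(self, item_values: Mapping[str, float]) -> float:
        sc = self.sum_score(item_values)
        if self.log_flag:
            return self.bias_factor * math.exp(self.intercept + self.slope * sc)
        return self.intercept + self.slope * sc

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "nutrient_id": self.nutrient_id,
            "unit": self.unit,
            "multipliers": {k: int(v) for k, v in self.multipliers.items()},
            "intercept": float(self.intercept),
            "slope": float(self.slope),
            "log_flag": bool(self.log_flag),
            "bias_factor": float(self.bias_factor),
            "r_squared": None if math.isnan(self.r_squared) else float(self.r_squared),
            "mse": None if math.isnan(self.mse) else float(self.mse),
            "notes": self.notes,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringModel":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            nutrient_id=doc["nutrient_id"],
            unit=doc.get("unit", ""),
            multipliers={str(k): int(v) for k, v in doc["multipliers"].items()},
            intercept=float(doc["intercept"]),
            slope=float(doc["slope"]),
            log_flag=bool(doc.get("log_flag", False)),
            bias_factor=float(doc.get("bias_factor", 1.0)),
            r_squared=float("nan") if doc.get("r_squared") is None else float(doc["r_squared"]),
            mse=float("nan") if doc.get("mse") is None else float(doc["mse"]),
            notes=str(doc.get("notes", "")),
        )


def optimize_multipliers(
    dataset: FitDataset,
    item_order: Sequence[str] | None = None,
    init: Mapping[str, int] | None = None,
    log_flag: bool = False,
) -> dict[str, int]:
    """Run the +-1 coordinate search and return the multiplier map.

    ``init`` may override the all-ones start per item.
    """
    reg = _regressor_for(dataset, item_order, init, log_flag)
    reg.fit(dataset.X, dataset.y.to_numpy())
    return dict(zip(dataset.X.columns, (int(v) for v in reg.multipliers_)))


def _regressor_for(dataset, item_order, init, log_flag) -> IntegerScoreRegressor:
    reg = IntegerScoreRegressor(log_target=log_flag, item_order=item_order)
    if init:
        inits = set(init.values())
        if len(inits) == 1:
            reg.set_params(init_multiplier=inits.pop())
        else:
            raise NotImplementedError(
                "per-item initial multipliers are not supported; "
                "use a uniform init_multiplier"
            )
    return reg


def fit_scoring_model(
    dataset: FitDataset,
    item_order: Sequence[str] | None = None,
    init: Mapping[str, int] | None = None,
    log_flag: bool = False,
) -> ScoringModel:
    """Fit a complete :class:`ScoringModel` for ``dataset``'s nutrient."""
    reg = _regressor_for(dataset, item_order, init, log_flag)
    reg.fit(dataset.X, dataset.y.to_numpy())
    return ScoringModel(
        nutrient_id=dataset.nutrient_id,
        unit=dataset.unit,
        multipliers=dict(zip(dataset.X.columns, (int(v) for v in reg.multipliers_))),
        intercept=reg.intercept_,
        slope=reg.slope_,
        log_flag=log_flag,
        bias_factor=reg.bias_factor_,
        r_squared=reg.r_squared_,
        mse=reg.mse_,
    )


def residual_diagnostics(
    model: ScoringModel, dataset: FitDataset, plot_path: str | Path | None = None
) -> pd.DataFrame:
    """Residuals against predictions on the original intake scale.

    Optionally renders the residual-versus-predicted scatter to
    ``plot_path``.
    """
    preds = np.array(
        [model.predict_from_features(row._asdict() if hasattr(row, "_asdict") else dict(row))
         for _, row in dataset.X.iterrows()]
    )
    resid = dataset.y.to_numpy(dtype=float) - preds
    out = pd.DataFrame({"predicted": preds, "residual": resid})
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(preds, resid, s=12)
        ax.axhline(0.0, color="grey", lw=1)
        ax.set_xlabel(f"predicted {model.nutrient_id} ({model.unit})")
        ax.set_ylabel("residual")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return out
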