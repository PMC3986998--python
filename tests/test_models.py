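"""Sum scores, the simple linear fit, the +-1 coordinate search and its
contracts, and scoring-model serialization."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from fiq16.core import encode_features
from fiq16.models import (
    DegenerateFitError,
    FitDataset,
    IntegerScoreRegressor,
    ScoringModel,
    bias_correction_factor,
    build_sum_score,
    fit_linear,
    fit_scoring_model,
    optimize_multipliers,
    residual_diagnostics,
)
from fiq16.scoring import published_fat_model
from fiq16.simulate import generate_known_model_data


# ---------------------------------------------------------------------------
# sum score


def test_worked_example_sum_score(codebook, example_response):
    """Published example: 2 + 0 + (-12) + 6 + 0*3 + (-5) = -9."""
    model = published_fat_model()
    features = encode_features(example_response, codebook)
    assert model.sum_score(features) == -9


def test_sum_score_zero_and_identity():
    assert build_sum_score({"a": 3.0}, {"a": 0}) == 0.0
    assert build_sum_score({"a": 3.0}, {"a": -4}) == -12.0


def test_sum_score_missing_item():
    with pytest.raises(KeyError, match="cheese"):
        build_sum_score({"a": 1.0}, {"a": 1, "cheese": 2})
    # zero-multiplier items may be absent
    assert build_sum_score({"a": 1.0}, {"a": 1, "b": 0}) == 1.0


# ---------------------------------------------------------------------------
# simple linear regression


def test_fit_linear_perfect_fit():
    x = np.array([0.0, 1, 2, 3, 4])
    intercept, slope, r2, mse = fit_linear(x, 2 + 3 * x)
    assert (intercept, slope) == pytest.approx((2.0, 3.0))
    assert r2 == pytest.approx(1.0)
    assert mse == pytest.approx(0.0, abs=1e-20)


def test_fit_linear_matches_normal_equations():
    """5-point dataset against the closed-form normal equations."""
    x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
    y = np.array([2.1, 2.9, 6.2, 7.8, 9.5])
    intercept, slope, r2, mse = fit_linear(x, y)
    n = 5
    slope_ref = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x**2).sum() - x.sum() ** 2)
    intercept_ref = y.mean() - slope_ref * x.mean()
    resid = y - intercept_ref - slope_ref * x
    assert slope == pytest.approx(slope_ref, abs=1e-12)
    assert intercept == pytest.approx(intercept_ref, abs=1e-12)
    assert mse == pytest.approx((resid**2).sum() / (n - 2), abs=1e-12)
    assert r2 == pytest.approx(1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum(), abs=1e-12)


def test_fit_linear_degenerate_scores():
    with pytest.raises(DegenerateFitError):
        fit_linear([2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0])


def test_fit_linear_log_requires_positive():
    with pytest.raises(ValueError, match="positive"):
        fit_linear([1.0, 2.0, 3.0], [1.0, 0.0, 2.0], log_flag=True)


def test_r2_near_zero_for_independent_target():
    rng = np.random.default_rng(5)
    x = rng.normal(size=2000)
    y = rng.normal(size=2000)
    _, _, r2, _ = fit_linear(x, y)
    assert r2 < 0.01


# ---------------------------------------------------------------------------
# bias correction


@pytest.mark.parametrize("mse,expected", [(0.0, 1.0), (2.0, math.e), (0.5, math.exp(0.25))])
def test_bias_correction_factor(mse, expected):
    assert bias_correction_factor(mse) == pytest.approx(expected)


def test_bias_correction_rejects_negative():
    with pytest.raises(ValueError):
        bias_correction_factor(-0.1)


# ---------------------------------------------------------------------------
# coordinate search


def test_single_item_terminates_at_init():
    """A single-item score is scale-free: any multiplier gives the same
    R-squared, so the search stays at the initial value."""
    ds = generate_known_model_data(100, {"a": 1}, 0, 1, 0.0, seed=0)
    m = optimize_multipliers(ds)
    assert m == {"a": 1}


def test_two_item_noise_free_recovers_ratio_and_grid_optimum():
    ds = generate_known_model_data(200, {"a": 2, "b": 1}, 5, 1.5, 0.0, seed=1)
    reg = IntegerScoreRegressor().fit(ds.X, ds.y.to_numpy())
    a, b = reg.multipliers_
    assert (a, b) == (2, 1)
    assert reg.r_squared_ == pytest.approx(1.0)
    # exhaustive small-grid oracle: no integer pair in [-5, 5]^2 beats it
    X = ds.X.to_numpy()
    y = ds.y.to_numpy()

    def r2_of(m):
        s = X @ np.array(m, float)
        if np.ptp(s) == 0:
            return -np.inf
        return float(np.corrcoef(s, y)[0, 1] ** 2)

    best = max(r2_of(m) for m in itertools.product(range(-5, 6), repeat=2))
    assert reg.r_squared_ == pytest.approx(best, abs=1e-12)


def test_search_contract_monotone_local_deterministic():
    ds = generate_known_model_data(300, {"a": 3, "b": 1, "c": -2}, 10, 2, 4.0, seed=11)
    reg = IntegerScoreRegressor().fit(ds.X, ds.y.to_numpy())
    hist = reg.r2_history_
    assert all(b >= a for a, b in zip(hist, hist[1:]))
    assert reg.is_local_optimum(ds.X, ds.y.to_numpy())
    reg2 = IntegerScoreRegressor().fit(ds.X, ds.y.to_numpy())
    assert np.array_equal(reg.multipliers_, reg2.multipliers_)
    assert (reg.intercept_, reg.slope_) == (reg2.intercept_, reg2.slope_)


def test_parameter_recovery_small():
    """Recovered weight ratios within one step of (3, 1, -2) across seeds."""
    truth = np.array([3.0, 1.0, -2.0])
    hits = 0
    for seed in range(20):
        ds = generate_known_model_data(500, {"a": 3, "b": 1, "c": -2}, 10, 2, 4.0, seed=seed)
        m = np.array(list(optimize_multipliers(ds).values()), float)
        ok = any(
            np.all(np.abs(sgn * m - k * truth) <= 1 + 1e-9)
            for k in range(1, 34)
            for sgn in (1, -1)
        )
        hits += ok
    assert hits >= 18


def test_scale_covariance_of_predictions():
    """Multiplying all multipliers by c and dividing the slope by c leaves
    predictions unchanged (only slope x multipliers is identifiable)."""
    features = {"a": 2.0, "b": 5.0}
    m1 = ScoringModel("x", "g", {"a": 2, "b": -3}, intercept=4.0, slope=0.6)
    m2 = ScoringModel("x", "g", {"a": 4, "b": -6}, intercept=4.0, slope=0.3)
    assert m1.predict_from_features(features) == pytest.approx(
        m2.predict_from_features(features)
    )


def test_fit_scoring_model_log_rejects_zero_targets():
    ds = generate_known_model_data(50, {"a": 1, "b": 1}, 0, 1, 0.0, seed=2)
    ds.y.iloc[0] = 0.0
    with pytest.raises(ValueError, match="positive"):
        fit_scoring_model(ds, log_flag=True)


def test_sex_as_separate_covariate_mode():
    rng = np.random.default_rng(8)
    n = 300
    X = pd.DataFrame(
        {
            "a": rng.integers(0, 8, n).astype(float),
            "sex": rng.integers(0, 2, n).astype(float),
        }
    )
    y = 2 * X["a"] - 4 * X["sex"] + rng.normal(0, 1, n)
    reg = IntegerScoreRegressor(sex_covariate="sex").fit(X, y.to_numpy())
    assert reg.sex_coef_ == pytest.approx(-4.0, abs=0.5)
    preds = reg.predict(X)
    assert np.corrcoef(preds, y)[0, 1] ** 2 > 0.9


def test_sklearn_estimator_protocol():
    reg = IntegerScoreRegressor(log_target=True, max_passes=10)
    cloned = clone(reg)
    assert cloned.get_params()["log_target"] is True
    assert cloned.get_params()["max_passes"] == 10


# ---------------------------------------------------------------------------
# diagnostics and serialization


def test_residuals_zero_for_perfect_fit(tmp_path):
    ds = generate_known_model_data(60, {"a": 2, "b": 1}, 5, 1.5, 0.0, seed=3)
    model = fit_scoring_model(ds)
    table = residual_diagnostics(model, ds)
    assert np.allclose(table["residual"], 0.0, atol=1e-9)


def test_residual_mean_zero_for_linear_model():
    ds = generate_known_model_data(200, {"a": 2, "b": 1}, 5, 1.5, 3.0, seed=4)
    model = fit_scoring_model(ds)
    table = residual_diagnostics(model, ds)
    assert table["residual"].mean() == pytest.approx(0.0, abs=1e-9)


def test_model_yaml_roundtrip_scores_identically(tmp_path):
    ds = generate_known_model_data(120, {"a": 2, "b": 1}, 5, 1.5, 2.0, seed=6)
    model = fit_scoring_model(ds)
    path = tmp_path / "model.yaml"
    model.to_yaml(path)
    back = ScoringModel.from_yaml(path)
    features = {"a": 3.0, "b": 4.0}
    assert back.predict_from_features(features) == model.predict_from_features(features)
    assert back == model


def test_scoring_model_integer_multipliers_enforced():
    with pytest.raises(ValueError, match="integer"):
        ScoringModel("x", "g", {"a": 1.5}, intercept=0.0, slope=1.0)
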