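# Methods

This note documents the models, defaults and design choices behind
`fiq16`, in the package's own words. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Instrument and codebook

The 16-FIQ has three question types: six categorical frequency questions
(meals/day; fast food, fruit, vegetable, sugar-rich foods, sweets), four
type choices (cooking fat or cream, spread on bread, dressing), and six
open-ended quantity questions (weekly dish counts for five dish groups;
milk dl/day, cheese and cold-cut slices/day by fat class, bread slices and
cereal dl/day by fibre class, beverage servings/day by sugar/alcohol
class). Sex is carried on each response because the scoring models use it.

The exact answer categories of the original instrument are distributed
separately from the published methods, so the packaged codebook
(`fiq16/data/codebook.yaml`) is a documented stand-in covering every
category the methods text and the worked example name. It is plain
configuration: ordinal categories carry a midpoint and a period (weekly
midpoints are divided by 7, monthly by 30 — the simplest defensible
constants), and a replacement codebook drops in without code change.
Responses are complete by contract; a missing answer is an error, never an
imputation.

## Nutrient estimation

Daily quantity per item = frequency/day × average portion weight (open
counts × per-unit weight). The spread rule adds one spread portion
(default 5 g) per bread slice when a spread is used, typed margarine vs
butter; the cooking-fat rule adds one portion (default 10 g, plus 10 g of
cream when cream is reported) per cooked dish, dishes counted per week;
the dressing rule adds one 10 g portion per day when a dressing is used.
Portions are configurable (`EstimationConfig`).

Energy uses the factors 37 kJ/g (fat), 17 kJ/g (carbohydrate and protein)
and 29 kJ/g (alcohol). Sucrose is treated as a subset of carbohydrate:
its grams get the factor 17 in the E% numerator but contribute to total
energy only once, through carbohydrate — counting sucrose energy
separately would break the identity fat+protein+carbohydrate+alcohol E% =
100, which the package asserts to 1e−9 whenever energy is positive.
Zero-energy responses are flagged rather than divided by zero, and
downstream comparisons skip them with a logged warning.

The packaged composition table (`fiq16/data/composition.csv`) contains
plausible fixture portion weights and nutrient densities for a Nordic
diet. It is not a transcription of any national food-composition
database; absolute nutrient outputs are fixture-dependent, and only the
scoring worked example is anchored to published constants. The
"meals per day" item maps to a `meal_average` entry with zero densities by
default, because main-meal energy is already captured by the dish-count
items; the entry exists as a configurable hook.

## Validation statistics

* **Spearman** via average ranks (`scipy.stats.spearmanr`), two-sided p
  from the t approximation, significance flagged at α = 0.05, no
  multiple-testing correction. Constant vectors are an explicit error.
* **Tertiles** are rank-based with stable (position-order) tie-breaking;
  group sizes differ by at most one with the larger groups at the lower
  end (77 → 26/26/25). Boundary ties therefore resolve deterministically
  to the lower tertile; an all-constant vector is split by position with
  a logged warning.
* **Exact/opposite agreement** come from the 3×3 cross-classification:
  diagonal share, and the (1,3)+(3,1) share.
* **Weighted kappa** is κ_w = 1 − Σw·o / Σw·e with expected counts from
  the marginals and w_ij = |i−j|/2 (linear, default) or ((i−j)/2)²
  (quadratic). The source material for this instrument does not say which
  weighting produced its published values, so the report records the
  scheme used. The implementation is cross-checked in the tests against
  both a brute-force expansion and scikit-learn's weighted Cohen kappa.

Food groups are compared as questionnaire frequency/day vs record g/day;
the 12 nutrient variables as questionnaire-estimated vs record intakes
(E% for macronutrients, mass/day otherwise), with tertile agreement and
kappa added on the nutrient side.

## Scoring models and the ±1 coordinate search

A scoring model is `SC = Σ m_i·x_i` with integer `m_i`, plus a simple
linear regression of the food-record intake on SC. Item values keep their
questionnaire units (dishes *per week*, slices *per day*, 0/1 type and
sex indicators) — this matches the worked example's arithmetic. Sex is by
default an ordinary scored item (male indicator with an integer
multiplier); modelling it as a separate regression covariate is available
via `sex_covariate=`.

Search conventions (the published description leaves them open; these are
the package's choices):

* all free multipliers start at 1 (`init_multiplier`);
* items are visited in fixed questionnaire/column order (`item_order`);
* +1 is tried before −1 and only strict R² improvement is accepted, so
  ties keep the current multiplier and the search is deterministic;
* safety caps: |m| ≤ 100 and ≤ 500 passes; exceeding either raises a
  non-convergence error rather than stopping silently.

**One step per item per pass.** A literal reading of the procedure would
exhaust each item (keep stepping while R² increases) before moving on.
That variant is available (`exhaust_items=True`) but is not the default,
because it can diverge: with mixed-sign true weights and an all-ones
start, R² along a single coordinate ray often increases monotonically
toward an asymptote (growing one multiplier merely dilutes the
not-yet-adjusted, wrong-sign items), driving that multiplier to the cap
before any other item is touched. Taking at most one ±1 step per item per
pass lets the multipliers co-evolve toward the correct ratio, preserves
every stated contract (accepted R² steps nondecreasing; termination only
at a configuration where no single ±1 change improves R²; determinism),
and recovers true integer-weight ratios reliably in the package's
parameter-recovery tests. Only the products slope·m_i are identifiable:
rescaling all multipliers and the slope inversely leaves predictions
unchanged, which the tests assert.

**Log transform.** The target may be regressed on the natural-log scale
(per-nutrient configuration, default off) to improve residual normality
and homoscedasticity; right-skewed intakes such as alcohol or vitamin D
are natural candidates (a normality check of the raw-scale residuals is
the suggested heuristic). Back-transformed predictions are multiplied by
exp(MSE/2); MSE is the regression mean squared error SSE/(n−2), the
residual-variance estimate standard regression software prints for a
simple linear model. Zero or negative targets make the transform an error
before fitting, never a silent drop.

**Published fat model.** The shipped fixture
(`fiq16/data/fat_model_published.yaml`) carries the published constants
(intercept 36.66, slope 0.45; multipliers +1 sausage dishes/week, −12
fruit portions/day, +1 cheese slices/day, +3 frankfurters/day, −5 male).
The butter-in-cooking multiplier is not recoverable from the retrieved
text and is set to 0 as a clearly labelled synthetic stand-in; the worked
example only exercises the no-butter answer, which contributes 0 points
for any value. The other six nutrient models must be refit or supplied by
the user. Negative predictions are clamped to 0 with a logged warning;
display rounding is one decimal, full precision is kept internally.

## Synthetic cohorts

`generate_cohort` emulates the paired-instrument measurement structure:
per participant and food group a latent habitual frequency is log-normal
(dietary intakes are right-skewed); the record observes it through the
mean of 7 multiplicative day factors (day SD 0.8 on the log scale); the
questionnaire observes it through multiplicative reporting noise and then
coarsens it into codebook categories and rounded counts. Defaults are the
validation study's conditions: n = 77 with a 52:25 male:female split, and
per-group target rank correlations set to that study's printed per-group
values (0.08–0.75). Latent means were chosen once as realistic daily
frequencies for a Nordic working-age cohort (e.g. ~1.2 fruit
portions/day, ~4 dl milk/day, ~3 cups coffee/day) with log-SD 0.6–1.0.

For a target rank correlation r_s, the reporting-noise SD is solved in
closed form: for a bivariate normal, r_s = (6/π)·asin(ρ/2), so the
required Pearson correlation of the log scales is ρ = 2·sin(π·r_s/6), and
with latent variance σ², record-side noise variance s_r² =
log(1 + (e^{day_sd²} − 1)/7), the reporting variance is
s_q² = σ⁴ / (ρ²(σ² + s_r²)) − σ². Unreachable targets (too high for the
given day noise) fall back to zero reporting noise; non-positive targets
use a very large noise SD.

What the generator does *not* emulate: correlated food groups (each group
is independent), systematic over/under-reporting bias, digit preference,
seasonal variation, or any real dietary pattern. Answer coarsening is
irreducible: even with zero noise, ordinal categories and integer counts
tie ranks, so realized correlations sit slightly below the analytic
target (the tests assert the noise-free limit as exact rank-identity up
to this coarsening, and the calibration check allows the stated ±0.1).
Passing tests therefore demonstrate the pipeline's statistical mechanics,
not the field validity of the questionnaire on real cohorts.

`generate_known_model_data` is the parameter-recovery harness: item
values uniform on 0–7 (plausible weekly counts), target = intercept +
slope·(Σ m_i·x_i) + Gaussian noise.

## Problem sizes used by the checks

The acceptance-style tests run at the sizes the contracts name: the
worked example at n = 1; oracle equivalence on 1000 random instances of
size 6–30; the search contract at n = 500 with 5 items; recovery with
true weights (3, 1, −2) at n = 500 over 100 seeded replicates; the
correlation calibration over 200 seeds at n = 77. The whole suite runs in
well under a minute on a laptop-class core.

## Known limitations

* Absolute nutrient estimates inherit the fixture composition table; they
  are internally consistent, not survey-grade.
* Only the fat scoring model ships with published constants; refit models
  depend on the cohort used to fit them.
* The tertile tie rule and the search conventions (init, order, strict
  improvement, one step per visit) are package conventions where the
  published description is silent; all are configurable and recorded in
  outputs where relevant.
* Cross-validation / Bland–Altman style model assessment is out of scope.
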