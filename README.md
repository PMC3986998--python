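# fiq16

Tools for a 16-item food intake questionnaire (16-FIQ): estimating daily
nutrient intake from the answers, validating the questionnaire against
7-day food records, and building pencil-and-paper scoring models that turn
a handful of answers into a nutrient-intake estimate.

## The problem

Food records and full food-frequency questionnaires measure diet well but
are too heavy for routine primary-care use. A 16-item screener is quick to
fill in, but its answers need three pieces of machinery before they are
useful to a nurse or dietitian:

1. **Nutrient estimation.** Each answer (a consumption frequency, a type
   choice, or an open count of slices/decilitres/servings) is converted to
   grams per day via an average portion weight, and multiplied by the
   item's nutrient densities. Three add-on rules handle fat that never
   appears as its own "food": spread (one portion per bread slice when a
   spread is used), cooking fat (one portion per cooked dish), and salad
   dressing (one portion per day when used). Energy is
   `kJ = 37·fat + 17·carbohydrate + 17·protein + 29·alcohol` (grams/day),
   and each macronutrient's energy share is
   `E% = grams × factor / kJ × 100`.
2. **Validation statistics.** Paired questionnaire/food-record intakes are
   compared with Spearman rank correlation, rank-based tertile
   cross-classification (exact and opposite-extreme agreement), and
   weighted kappa (linear weights by default, quadratic available).
3. **Scoring models.** For a nutrient, selected item values `x_i` get small
   integer multipliers `m_i`; the sum score `SC = Σ m_i·x_i` is the single
   regressor in a simple linear model `intake = a + b·SC` (optionally on
   the natural-log scale, back-transformed with the multiplicative bias
   correction `exp(MSE/2)`). The multipliers are found by a deterministic
   ±1 coordinate hill climb that accepts only strict R² improvements and
   stops at a ±1-local optimum. The search is exposed as the scikit-learn
   estimator `IntegerScoreRegressor` (`fit`/`predict`/`get_params`).

Because no participant-level cohort is distributed with the questionnaire,
the package ships a synthetic paired-cohort generator
(`fiq16.simulate`) whose per-food-group rank correlations are tunable, so
the whole pipeline is testable end to end.

## Worked example

The shipped published fat model estimates total fat intake (E%) from six
answers. For a male participant reporting 2 sausage dishes/week, no butter
in cooking, 1 fruit portion/day, 6 cheese slices/day and no frankfurters:

```python
>>> import fiq16
>>> codebook = fiq16.load_codebook()
>>> from fiq16.scoring import example_fat_response, published_fat_model, score_response
>>> response = example_fat_response(codebook)
>>> model = published_fat_model()
>>> features = fiq16.encode_features(response, codebook)
>>> model.sum_score(features)
-9.0
>>> round(score_response(model, response, codebook), 1)
32.6
```

The sum score is `2·1 + 0 + 1·(−12) + 6·1 + 0·3 + (−5) = −9` points, and
the model `36.66 + 0.45·SC` gives an estimated fat intake of 32.6 % of
energy — a little under the typical population mean, driven down by the
daily fruit portion.

The full pipeline is also available from the shell:

```bash
fiq16 simulate --n 77 --seed 1 --output-dir out
fiq16 estimate --responses out/responses.csv --output-dir out
fiq16 validate --responses out/responses.csv --records out/food_records.csv --output-dir out
fiq16 fit-models --responses out/responses.csv --records out/food_records.csv --output-dir out
fiq16 score --responses out/responses.csv --output-dir out
```

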