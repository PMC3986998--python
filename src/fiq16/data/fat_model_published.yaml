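# Published fat-intake scoring model (energy-percent of total fat).
#
# Constants as printed with the published scoring table's worked example:
# intake E% = 36.66 + 0.45 * SC, with SC the integer-weighted sum of
# sausage dishes/week (x1), fruit portions/day (x-12), cheese slices/day
# (x1), frankfurters/day (x3), a butter-in-cooking indicator, and a male
# indicator (-5).
#
# The butter-in-cooking multiplier is NOT recoverable from the retrieved
# text (the full scoring grid is distributed as an image); the worked
# example only exercises the "no butter" answer, which contributes 0 points
# for any multiplier.  It is therefore set to 0 here as a synthetic
# stand-in and flagged in `notes`.  All other constants are the published
# ones.
nutrient_id: fat
unit: E%
multipliers:
  sausage_dishes_per_week: 1
  butter_in_cooking: 0
  fruit_portions_per_day: -12
  cheese_slices_per_day: 1
  frankfurters_per_day: 3
  male: -5
intercept: 36.66
slope: 0.45
log_flag: false
bias_factor: 1.0
r_squared: null
mse: null
notes: >-
  Published fat model. The butter_in_cooking multiplier is a synthetic
  stand-in (0): the source prints only the no-butter case of the worked
  example, which scores 0 points regardless of the multiplier.
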