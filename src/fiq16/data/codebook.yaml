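# Default codebook for the 16-item food intake questionnaire.
#
# This is a documented stand-in for the original instrument's answer
# categories (which are distributed separately from the published methods):
# it covers every category the methods text and the published worked example
# name, and it is replaceable configuration -- an exact transcription of the
# original categories drops in without code change.
#
# Ordinal midpoints are events per `per` (day/week/month); the per-day rate
# divides weekly midpoints by 7 and monthly midpoints by 30.
version: 1
items:
  meals_per_day:
    kind: ordinal
    unit: meals/day
    categories:
    - {label: "1-2", midpoint: 1.5, per: day}
    - {label: "3-4", midpoint: 3.5, per: day}
    - {label: "5-6", midpoint: 5.5, per: day}
    - {label: "7_or_more", midpoint: 7.5, per: day}
  fastfood:
    kind: ordinal
    unit: times/day
    categories:
    - {label: "never", midpoint: 0, per: day}
    - {label: "less_than_once_a_month", midpoint: 0.5, per: month}
    - {label: "1-3_per_month", midpoint: 2, per: month}
    - {label: "1_per_week", midpoint: 1, per: week}
    - {label: "2-3_per_week", midpoint: 2.5, per: week}
    - {label: "4-6_per_week", midpoint: 5, per: week}
    - {label: "1_per_day", midpoint: 1, per: day}
    - {label: "2_or_more_per_day", midpoint: 2.5, per: day}
  fruit:
    kind: ordinal
    unit: portions/day
    categories:
    - {label: "none", midpoint: 0, per: day}
    - {label: "less_than_1_per_day", midpoint: 0.5, per: day}
    - {label: "1_per_day", midpoint: 1, per: day}
    - {label: "2_per_day", midpoint: 2, per: day}
    - {label: "3_per_day", midpoint: 3, per: day}
    - {label: "4_or_more_per_day", midpoint: 4.5, per: day}
  vegetable:
    kind: ordinal
    unit: portions/day
    categories:
    - {label: "none", midpoint: 0, per: day}
    - {label: "less_than_1_per_day", midpoint: 0.5, per: day}
    - {label: "1_per_day", midpoint: 1, per: day}
    - {label: "2_per_day", midpoint: 2, per: day}
    - {label: "3_per_day", midpoint: 3, per: day}
    - {label: "4_or_more_per_day", midpoint: 4.5, per: day}
  sugar_rich:
    kind: ordinal
    unit: times/day
    categories:
    - {label: "never", midpoint: 0, per: day}
    - {label: "less_than_once_a_month", midpoint: 0.5, per: month}
    - {label: "1-3_per_month", midpoint: 2, per: month}
    - {label: "1_per_week", midpoint: 1, per: week}
    - {label: "2-3_per_week", midpoint: 2.5, per: week}
    - {label: "4-6_per_week", midpoint: 5, per: week}
    - {label: "1_per_day", midpoint: 1, per: day}
    - {label: "2_or_more_per_day", midpoint: 2.5, per: day}
  sweets:
    kind: ordinal
    unit: times/day
    categories:
    - {label: "never", midpoint: 0, per: day}
    - {label: "less_than_once_a_month", midpoint: 0.5, per: month}
    - {label: "1-3_per_month", midpoint: 2, per: month}
    - {label: "1_per_week", midpoint: 1, per: week}
    - {label: "2-3_per_week", midpoint: 2.5, per: week}
    - {label: "4-6_per_week", midpoint: 5, per: week}
    - {label: "1_per_day", midpoint: 1, per: day}
    - {label: "2_or_more_per_day", midpoint: 2.5, per: day}
  cooking_fat:
    kind: choice
    choices: [vegetable_oil_or_margarine, butter_or_butter_spread, none, other]
  cream_in_cooking:
    kind: choice
    choices: ["yes", "no"]
  spread:
    kind: choice
    choices: [vegetable_margarine, butter_or_butter_spread, none]
  dressing:
    kind: choice
    choices: [oil_based, other, none]
  dishes:
    kind: count
    unit: dishes/week
    classes: [fish, sausage, chicken, meat, vegetable]
  milk:
    kind: count
    unit: dl/day
    classes: [skimmed, semi_skimmed, whole]
  cheese:
    kind: count
    unit: slices/day
    classes: [low_fat, regular]
  coldcuts:
    kind: count
    unit: slices/day
    classes: [low_fat, regular, frankfurter]
  bread_and_cereals:
    kind: count
    unit: slices_or_dl/day
    classes: [bread_rye_crisp, bread_multigrain, bread_white, cereal_porridge, cereal_other]
  beverages:
    kind: count
    unit: servings/day
    classes: [tea, coffee, soft_drink, sugar_sweetened_juice, fruit_juice, beer, wine, spirits]
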