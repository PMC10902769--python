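# mealrecall

A toolkit for **generic meal-based dietary recall**: instead of enumerating
every food eaten, respondents pick whole-meal images from a bank of *generic
meals* derived from weighed-diary survey data. The package covers the whole
method lifecycle plus the statistical battery used to evaluate it against a
reference 24-hour recall:

- **`mealrecall.nutrients`** — nutrient vectors with explicit bases
  (per 100 g / per day / per portion), meal profiles, %TEI shares,
  sodium-to-salt conversion.
- **`mealrecall.nrf`** — NRF9.3 nutrient-profiling score (per 100 kcal,
  capped encouraged terms, uncapped limited terms; reference values are
  editable config).
- **`mealrecall.derive`** — generic-meal bank derivation: meal typing,
  feature construction (NRF score + food-group weight fractions, z-scored),
  k-medoids clustering (PAM BUILD+SWAP with seeded restarts), per-100 g mean
  cluster profiles and seven septile portion weights per generic meal.
- **`mealrecall.recall`** — the recall scoring engine: image/portion answers
  (displayed septiles 2/4/6 plus a smaller/same/larger follow-up) resolve to
  one of seven portions; beverages use counts; daily totals are summed with
  none-of-the-above fallbacks tracked.
- **`mealrecall.misreport`** — EI:BMR plausibility screening with
  age/sex-banded BMR equations (packaged, editable coefficient table) and
  0.96 / 2.49 cutoffs.
- **`mealrecall.compare`** — the paired-method evaluation battery: Wilcoxon
  signed-rank (exact sign-assignment distribution for small n, tie- and
  continuity-corrected normal otherwise), effect size r with labels,
  Bland-Altman limits of agreement, Spearman correlation with labels,
  cross-classification of quartiles, guideline categorisation and agreement,
  percentage differences and their median/IQR summary (type-7 quantiles
  throughout).
- **`mealrecall.synth`** — synthetic cohorts with known ground truth:
  energy-consistent food tables, templated multi-food diaries, a noisy
  comparator instrument and a structurally-erroneous generic recall
  (meal mismatch + portion quantisation + optional bias multiplier).
- **`mealrecall.io` / `mealrecall.cli`** — CSV/JSON formats with provenance
  headers and the command-line pipeline.

## CLI

The whole pipeline chains on synthetic data:

```sh
mealrecall simulate --seed 1 --out sim/
mealrecall derive --diary sim/diary.csv --foods sim/foods.csv --seed 1 --out bank.json
mealrecall score  --bank sim/bank.json --responses sim/responses.json --out intakes_generic.csv
mealrecall screen --participants participants.csv --intakes sim/intakes_24hr.csv --out flags.csv
mealrecall compare --a sim/intakes_24hr.csv --b sim/intakes_generic.csv --out results/
```

`compare` writes `comparison.tsv` (one row per nutrient: medians, percent
difference, Wilcoxon P, effect size, Bland-Altman triple, Spearman rho,
quartile cross-classification) and `summary.json`; pass
`--guidelines g.json --participants p.csv` to add guideline-category
agreement (an example table ships at
`src/mealrecall/data/guidelines_example.json`).

Exit codes: 0 success, 1 validation/data error, 2 usage error.

## Notes

- All quantiles are linear-interpolation (type-7); boundary values in
  classification rules always fall to the lower category; Bland-Altman
  differences are reference-minus-test while percentage differences are
  test-relative-to-reference.
- Every stochastic component is driven by a single integer seed; cohorts
  and banks regenerate bit-identically.
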