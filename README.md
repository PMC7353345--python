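# fopl — the Israeli dual front-of-package labeling system

Israel pairs a **mandatory warning ("red") label** — one mark for each of
sugars, sodium and saturated fat strictly above a regulatory threshold
(per 100 g for solids, per 100 mL for beverages; 0–3 marks per product) —
with a **voluntary positive ("green") label** for foods in their natural form
or minimally processed, with no food additives, under category-specific
criteria (additive whitelists, per-100 g maxima with explicit ≤/< semantics,
processing-flag rules, a plant-group-only combination rule, and the
requirement that an endorsed product never exceeds a warning threshold).

This package is for food-policy analysts and nutrition researchers who need
the full rule system as tested, reusable code: both label engines, the
machine-readable criteria tables (bundled as YAML, user-replaceable), a
calibrated synthetic food-composition database with known ground-truth labels
standing in for the non-public national data, and prevalence analysis of the
resulting label landscape. It also implements the legacy EFSHARIBARI
("Healthy is Possible") bread endorsement: whole-grain ≥ 80 %,
sodium ≤ 400 mg, energy ≤ 250 kcal per 100 g.

See `docs/methods.md` for the model, the criteria-table interpretation
choices and the calibration derivation.

## Worked example

```python
import fopl

rs = fopl.default_ruleset()          # bundled criteria + stage-1 warning thresholds

yogurt = fopl.FoodProduct(
    product_id="Y1", name="plain yogurt 3%",
    category=fopl.Category.dairy, subcategory="fermented_milk",
    nutrients=fopl.NutrientProfile(total_fat_g=3.0, sat_fat_g=2.0,
                                   sugars_g=4.6, sodium_mg=46),
)
print(fopl.classify_positive(yogurt, rs).eligible)        # True

sweetened = yogurt.model_copy(update={"additive_tokens": frozenset({"sweetener"})})
print(fopl.classify_positive(sweetened, rs).failure_reasons)
# (<FailureReason.additive_violation: 'additive_violation'>,)
```

The same thing end to end from the shell, on a 2,000-product synthetic table:

```sh
fopl run --n 2000 --seed 42 --out-dir out
```

writes `products.csv`, `truth.csv`, `decisions.csv` and `summary.json` under
`out/` and prints the summary:

```
INFO rule set israeli_positive_v1, warning stage stage1_2020, seed 42
INFO labeled 2000 products; positive 20.1%, warning 12.6%
{
 "n_total": 2000,
 "pct_positive": 20.1,
 "pct_warning": 12.6,
 "pct_none": 67.3,
 ...
}
```

20.1 % of the synthetic products are eligible for the positive label and
12.6 % carry at least one warning — binomial noise around the calibrated
expectations of 19.8 % and 14.1 %, the proportions reported for the national
product data. `fopl generate`, `fopl warn`, `fopl label` and
`fopl summarize` expose the individual pipeline stages; `fopl summarize`
also tabulates observed-vs-published deviations for every reported metric.

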