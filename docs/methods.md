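# Methods

## The labeling model

Israel's front-of-package system uses two independent marks:

* **Warning ("red") label** — mandatory. A product carries one mark for each
  of total sugars, sodium and saturated fat whose declared amount *strictly
  exceeds* a regulatory threshold (0–3 marks total). Energy never triggers a
  warning. Solids are judged per 100 g, beverages per 100 mL; a second
  regulatory stage tightened the thresholds component-wise:

  | stage | basis | sugars (g) | sodium (mg) | sat. fat (g) |
  |---|---|---|---|---|
  | 1 (2020) | solids / 100 g | 13.5 | 500 | 5 |
  | 1 (2020) | beverages / 100 mL | 5 | 400 | 3 |
  | 2 (2021) | solids / 100 g | 10 | 400 | 4 |
  | 2 (2021) | beverages / 100 mL | 5 | 300 | 3 |

  The engine treats these as configuration (`fopl/rulesets/israeli_warning_stage{1,2}.yaml`);
  user threshold files are accepted. "Exceeds" is read literally: a value
  exactly at the threshold does **not** trigger the mark.

* **Positive ("green") label** — voluntary, category-specific, and grounded in
  processing level rather than a nutrient score. A product is eligible iff it
  matches a criteria row for its declared category/subcategory and passes every
  check:

  1. **Additive whitelist.** "No additives except …" semantics: every declared
     controlled-vocabulary token must be whitelisted by the row; an unknown
     token is a violation (regulatory conservatism). Water never counts as an
     additive in plant-based foods.
  2. **Numeric limits**, per 100 g, at the row's explicit comparison:
     inclusive for "≤" (cheese sodium ≤ 200 mg passes at exactly 200), strict
     for "<" (legume spreads fail at exactly 7 g total fat). No rounding is
     applied; values are compared at input precision.
  3. **Processing flags.** Row-specific prohibitions (fruits: fried, juiced,
     dried — reconstituted freeze-dried excepted — and sweetened/jam forms)
     and requirements (eggs, fresh fish and fresh poultry must be raw/fresh).
     Nutritional enrichment disqualifies *every* category.
  4. **Combination rule.** Mixtures are allowed only among grains, legumes,
     fruits, vegetables and nuts/seeds. The mixture is judged against a
     synthesized rule: union of the component base rules' whitelists and flag
     prohibitions, with the most restrictive numeric limit applied once to the
     whole product.
  5. **Warning consistency.** An endorsed product may not exceed any warning
     threshold, and all three warning nutrients must be declared.

  All checks always run (no short-circuit) so failure-reason tallies over a
  table are unbiased. A nutrient that a limit applies to but that is not
  declared disqualifies: endorsement requires demonstrated compliance, whereas
  a warning requires positive evidence of exceedance — the asymmetry is
  deliberate.

The two labels are mutually exclusive by construction (check 5), and a product
can carry neither: absence of a warning is not an endorsement.

The pre-existing **"Healthy is Possible" (EFSHARIBARI) bread label** —
whole-grain share ≥ 80 % of grain, sodium ≤ 400 mg and energy ≤ 250 kcal per
100 g, all boundaries inclusive — is kept as a separate legacy classifier
(`classify_efsharibari_bread`), not folded into the criteria table, because it
predates the committee criteria and applies to a category (bread) the table
does not cover.

### Criteria-table interpretation choices

* All table limits are per 100 g edible portion, including liquids (the table
  basis is per 100 g); only *warning* evaluation switches to per 100 mL for
  beverages. Soy drink's sodium ≤ 50 mg is therefore evaluated per 100 g.
* "Total fat ≤ 5 %" (fermented milk) and "< 7 %" (legume spreads) are read as
  g per 100 g (percent by mass).
* Rows that defer to food standards with no further criteria (liquid milk,
  whole pasta, tea) are modeled as additive/flag-only rules with no numeric
  limits; standards cross-references are out of scope.
* The whole-grain-flour row, whose additive/limit cells are blank, is modeled
  as "no additives, no numeric limits", mirroring the adjacent legume-flour
  row.
* The bundled rule file has 25 rows: the five named oils share one rule, and
  every other subcategory line is a distinct rule.
* Category and additive tokens are *declared* by the data provider; there is
  no ingredient-text parsing. The warning-consistency clause is applied
  uniformly, including to rows with no numeric limits (e.g. nuts, whose
  natural saturated fat can exceed the warning threshold).

## Synthetic database and calibration

The national food-composition and consumption data behind the published
prevalence figures are not public, so the generator emulates a product table
with known ground truth. It is *constructive*: a product intended to be
positive is drawn inside every applicable limit and warning threshold by a
relative margin (default 5 %); an intended-warning product is drawn 5–100 %
above at least one threshold; an intended-neither product in a ruled category
starts rule-compliant and is broken in exactly one way (a non-whitelisted
additive, an enrichment flag, or a limit exceedance kept below the warning
threshold), while "other"-category products below all thresholds are neither
by definition. Classification therefore reproduces the intended label with
probability 1, not statistically — the round-trip test asserts 100 % at
n = 20,000. The margin also guarantees no generated value sits exactly on a
threshold; boundary behavior is covered by dedicated fixtures instead.

The default mix back-calculates each reporting group's share of all products
from the published figures: with overall positive share p = 0.198, positive-set
composition c_g (0.54 fruits & vegetables, 0.20 dairy, 0.14 grains, 0.11
meat/poultry/fish/egg, 0.01 legumes) and within-group eligibility rate r_g
(0.572 dairy, 0.378 meat group, 0.32 grains), the group share is
share_g = p·c_g / r_g. The fruits & vegetables and legumes within-group rates
are not published; they are set here to 0.80 and 0.66 — assumptions chosen so
all derived shares are feasible, and documented as such. The resulting mix is
≈ {dairy .069, meat .058, grains .087, fruits & vegetables .134, legumes .003,
other .650}; group shares are split evenly over the group's concrete
categories (eggs/fish/poultry; fruits/vegetables). Warning-labeled products
are confined to "other" at rate 0.141/0.650 ≈ 0.217, reproducing the overall
warning share of 14.1 %. These identities hold exactly in expectation
(`SyntheticConfig.expected_positive_share()` returns 0.198 in closed form);
a finite sample recovers them within binomial error.

What the generator does **not** emulate: real nutrient distributions (uniform
within compliance regions — labels depend only on threshold position),
survey weights, portion sizes, consumption frequencies, reformulation
dynamics, or warning-labeled products inside the named food groups. Passing
tests therefore demonstrate the correctness of the rule engines and the
internal consistency of the published proportions, not distributional realism.

## Numerical and design notes

* Comparisons are exact floating-point comparisons; percentages are computed
  unrounded and rounded half-up to one decimal only at presentation.
* Missing table cells load as absent (`None`), never zero; writers round-trip
  absence losslessly.
* Salt-to-sodium conversion uses 393.4 mg sodium per g NaCl (atomic-mass
  ratio 22.99/58.44).
* Mixture products use the sentinel category `mixture` with an explicit
  component set; a mixture whose components all lack a base rule cannot match.
* Reproducibility: one `numpy` generator seeded from the config drives all
  sampling; the same config yields byte-identical output tables.
* Default problem size for the calibrated-recovery checks is n = 20,000
  products, which the full pipeline processes in a few seconds.

## Known limitations

* The "salad" subcategory under tahini is modeled as a tahini-spread rule
  only; the scope of the original term is undefined.
* Rules that defer to national standards (milk, pasta, tea, tofu gelling
  agents "as allowed by standards") are only as strict as the fields modeled.
* Per-serving evaluation, ingredient NLP, allergen/kashrut handling and label
  artwork are out of scope.
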