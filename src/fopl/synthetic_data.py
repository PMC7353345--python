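"""Synthetic food-composition database with known ground-truth labels.

The national product database behind the published prevalence figures is not
public, so this module emulates it: products are drawn per category with an
*intended* label (positive / warning / neither) and composed constructively so
the label engines are guaranteed to reproduce the intention — nutrients sit a
relative ``margin`` inside or outside every relevant threshold, additives stay
within (or deliberately break) the whitelist, and processing flags follow suit.

The default configuration back-calculates the category mix from the published
figures: with an overall positive-eligibility share p, positive-set composition
c_g and within-group eligibility rate r_g, each group's share of all products
is p * c_g / r_g. The published figures give r_g for dairy, meat and grains;
the fruits & vegetables and legumes rates are not published and are set here as
documented assumptions (0.80 and 0.66). The residual share is "other", where
all warning-labeled products are placed at the rate that reproduces the overall
warning share. Nutrient values are uniform within their compliance regions —
label decisions depend only on threshold position, not distribution shape.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .food_model import (
    Category,
    CategoryRule,
    Comparison,
    FoodProduct,
    LabelClass,
    NutrientProfile,
    ProcessingFlag,
    RuleSet,
    default_ruleset,
)
from .prevalence import (
    FRUITS_VEGETABLES,
    GRAINS,
    LEGUMES,
    MEAT_FISH_EGG,
    MILK_DAIRY,
    OTHER,
)

#: Published overall shares (fractions of all products).
OVERALL_POSITIVE = 0.198
OVERALL_WARNING = 0.141

#: Published composition of the positive-eligible set (fractions).
POSITIVE_COMPOSITION: Mapping[str, float] = {
    FRUITS_VEGETABLES: 0.54,
    MILK_DAIRY: 0.20,
    GRAINS: 0.14,
    MEAT_FISH_EGG: 0.11,
    LEGUMES: 0.01,
}

#: Published within-group positive-eligibility rates.
WITHIN_GROUP_RATES: Mapping[str, float] = {
    MILK_DAIRY: 0.572,
    MEAT_FISH_EGG: 0.378,
    GRAINS: 0.32,
}

#: Within-group rates the publication does not report — assumptions, chosen so
#: every derived share is feasible.
FREE_RATES: Mapping[str, float] = {
    FRUITS_VEGETABLES: 0.80,
    LEGUMES: 0.66,
}

#: Concrete categories drawn (uniformly) for each reporting group.
GROUP_CATEGORIES: Mapping[str, tuple[Category, ...]] = {
    MILK_DAIRY: (Category.dairy,),
    MEAT_FISH_EGG: (Category.eggs, Category.fish, Category.poultry),
    GRAINS: (Category.grains,),
    LEGUMES: (Category.legumes,),
    FRUITS_VEGETABLES: (Category.fruits, Category.vegetables),
    OTHER: (Category.other,),
}

#: An additive token no positive rule whitelists — the generic violation device.
FORBIDDEN_TOKEN = "preservative"


class GroundTruthRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    product_id: str
    intended_label: LabelClass
    category: Category


class SyntheticConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_products: int = Field(ge=0)
    seed: int = 42
    category_mix: Mapping[Category, float]
    p_positive_given_category: Mapping[Category, float]
    p_warning_given_category: Mapping[Category, float]
    margin: float = Field(0.05, gt=0, lt=1)

    @model_validator(mode="after")
    def _consistent(self) -> "SyntheticConfig":
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_mix must sum to 1 (got {total})")
        for cat in self.category_mix:
            p_pos = self.p_positive_given_category.get(cat, 0.0)
            p_warn = self.p_warning_given_category.get(cat, 0.0)
            if not (0.0 <= p_pos <= 1.0 and 0.0 <= p_warn <= 1.0):
                raise ValueError(f"probabilities for {cat.value} must lie in [0,1]")
            if p_pos + p_warn > 1.0 + 1e-12:
                raise ValueError(f"p_positive + p_warning > 1 for {cat.value}")
        return self

    def expected_positive_share(self) -> float:
        return sum(
            share * self.p_positive_given_category.get(cat, 0.0)
            for cat, share in self.category_mix.items()
        )

    def expected_warning_share(self) -> float:
        return sum(
            share * self.p_warning_given_category.get(cat, 0.0)
            for cat, share in self.category_mix.items()
        )


def derive_category_mix(
    overall_positive: float,
    positive_composition: Mapping[str, float],
    within_group_rates: Mapping[str, float],
    free_rates: Mapping[str, float],
) -> dict[str, float]:
    """Back-calculate each reporting group's share of all products.

    share_g = overall_positive * composition_g / rate_g, with the rate taken
    from the published within-group table or, where unpublished, from
    ``free_rates``. The residual share goes to "other". Raises if any share is
    negative or the known shares already exceed 1.
    """
    rates = {**free_rates, **within_group_rates}
    shares: dict[str, float] = {}
    for group, comp in positive_composition.items():
        rate = rates.get(group)
        if rate is None or rate <= 0:
            raise ValueError(f"no positive within-group rate for {group!r}")
        share = overall_positive * comp / rate
        if share < 0:
            raise ValueError(f"negative share for {group!r}")
        shares[group] = share
    known = sum(shares.values())
    if known > 1.0 + 1e-12:
        raise ValueError(f"known group shares sum to {known} > 1")
    shares[OTHER] = 1.0 - known
    return shares


def default_config(n_products: int = 20_000, seed: int = 42, margin: float = 0.05) -> SyntheticConfig:
    """The calibrated study-condition configuration: group mix back-calculated
    from the published figures, warning products confined to "other" at the
    rate that reproduces the overall warning share."""
    group_shares = derive_category_mix(
        OVERALL_POSITIVE, POSITIVE_COMPOSITION, WITHIN_GROUP_RATES, FREE_RATES
    )
    rates = {**FREE_RATES, **WITHIN_GROUP_RATES}
    mix: dict[Category, float] = {}
    p_pos: dict[Category, float] = {}
    p_warn: dict[Category, float] = {}
    for group, share in group_shares.items():
        cats = GROUP_CATEGORIES[group]
        for cat in cats:
            mix[cat] = share / len(cats)
            p_pos[cat] = rates.get(group, 0.0)
            p_warn[cat] = 0.0
    p_warn[Category.other] = OVERALL_WARNING / group_shares[OTHER]
    return SyntheticConfig(
        n_products=n_products,
        seed=seed,
        category_mix=mix,
        p_positive_given_category=p_pos,
        p_warning_given_category=p_warn,
        margin=margin,
    )


# ---------------------------------------------------------------------------
# Constructive product generation
# ---------------------------------------------------------------------------

_WARN_FIELDS = ("sugars_g", "sodium_mg", "sat_fat_g")


def _compliant_nutrients(
    rule: Optional[CategoryRule],
    warn: Mapping[str, float],
    rng: np.random.Generator,
    margin: float,
    category: Category,
) -> dict[str, float]:
    """Draw a full nutrient profile strictly inside every applicable limit and
    every warning threshold (by the relative margin)."""
    m = margin
    limits = rule.max_limits if rule is not None else {}

    def cap(field: str) -> float:
        ub = (1 - m) * warn[field] if field in warn else np.inf
        if field in limits:
            ub = min(ub, (1 - m) * limits[field].value)
        return ub

    nutrients: dict[str, float] = {
        "energy_kcal": float(rng.uniform(20, 400)),
        "sugars_g": float(rng.uniform(0, cap("sugars_g"))),
        "sodium_mg": float(rng.uniform(0, cap("sodium_mg"))),
    }
    tf_limit = limits.get("total_fat_g")
    sf_cap = cap("sat_fat_g")
    if tf_limit is not None:
        tf = float(rng.uniform(0, (1 - m) * tf_limit.value))
        sf = float(rng.uniform(0, min(tf, sf_cap)))
    else:
        sf = float(rng.uniform(0, sf_cap))
        tf = sf + float(rng.uniform(0, 5))
    nutrients["total_fat_g"] = tf
    nutrients["sat_fat_g"] = sf
    if category is Category.grains:
        nutrients["whole_grain_pct"] = 100.0
    return nutrients


def _positive_product(
    pid: str, category: Category, rs: RuleSet, rng: np.random.Generator, margin: float
) -> FoodProduct:
    rules = rs.rules_for(category)
    if not rules:
        raise ValueError(f"cannot generate a positive product for {category.value!r}: no rule")
    rule = rules[int(rng.integers(len(rules)))]
    warn = rs.warning_thresholds.basis_for(rule.is_beverage)
    nutrients = _compliant_nutrients(rule, warn, rng, margin, category)
    additives: frozenset[str] = frozenset()
    if rule.allowed_additives and rng.random() < 0.5:
        additives = frozenset({str(rng.choice(sorted(rule.allowed_additives)))})
    return FoodProduct(
        product_id=pid,
        name=f"synthetic {category.value} ({rule.subcategory_key})",
        category=category,
        subcategory=rule.subcategory_key,
        is_beverage=rule.is_beverage,
        nutrients=NutrientProfile(**nutrients),
        additive_tokens=additives,
        processing_flags=rule.required_flags,
    )


def _warning_product(
    pid: str, category: Category, rs: RuleSet, rng: np.random.Generator, margin: float
) -> FoodProduct:
    m = margin
    warn = rs.warning_thresholds.solids
    to_exceed = {_WARN_FIELDS[int(rng.integers(3))]}
    for field in _WARN_FIELDS:
        if field not in to_exceed and rng.random() < 0.25:
            to_exceed.add(field)
    values: dict[str, float] = {}
    for field in _WARN_FIELDS:
        t = warn[field]
        if field in to_exceed:
            values[field] = float(rng.uniform((1 + m) * t, 2 * t))
        else:
            values[field] = float(rng.uniform(0, (1 - m) * t))
    values["total_fat_g"] = values["sat_fat_g"] + float(rng.uniform(0, 5))
    values["energy_kcal"] = float(rng.uniform(50, 600))
    return FoodProduct(
        product_id=pid,
        name=f"synthetic {category.value} (warning)",
        category=category,
        nutrients=NutrientProfile(**values),
    )


def _neither_product(
    pid: str, category: Category, rs: RuleSet, rng: np.random.Generator, margin: float
) -> FoodProduct:
    m = margin
    rules = rs.rules_for(category)
    if not rules:
        # no positive rule -> below all warning thresholds is already "neither"
        warn = rs.warning_thresholds.solids
        nutrients = {f: float(rng.uniform(0, (1 - m) * warn[f])) for f in _WARN_FIELDS}
        nutrients["total_fat_g"] = nutrients["sat_fat_g"] + float(rng.uniform(0, 5))
        nutrients["energy_kcal"] = float(rng.uniform(20, 400))
        return FoodProduct(
            product_id=pid,
            name=f"synthetic {category.value} (plain)",
            category=category,
            nutrients=NutrientProfile(**nutrients),
        )

    # start from a rule-compliant draw, then break the positive rule exactly once
    base = _positive_product(pid, category, rs, rng, margin)
    rule = next(r for r in rules if r.subcategory_key == base.subcategory)
    warn = rs.warning_thresholds.basis_for(rule.is_beverage)

    modes = ["additive", "flag"]
    violable: list[str] = []
    for field, limit in rule.max_limits.items():
        hi = 2 * limit.value
        if field in warn:
            hi = min(hi, (1 - m) * warn[field])
        if hi > (1 + m) * limit.value and limit.value > 0:
            violable.append(field)
    if violable:
        modes.append("limit")
    mode = modes[int(rng.integers(len(modes)))]

    if mode == "additive":
        return base.model_copy(update={"additive_tokens": base.additive_tokens | {FORBIDDEN_TOKEN}})
    if mode == "flag":
        # nutritional enrichment disqualifies every category
        return base.model_copy(
            update={"processing_flags": base.processing_flags | {ProcessingFlag.enriched}}
        )
    field = violable[int(rng.integers(len(violable)))]
    limit = rule.max_limits[field]
    hi = 2 * limit.value
    if field in warn:
        hi = min(hi, (1 - m) * warn[field])
    value = float(rng.uniform((1 + m) * limit.value, hi))
    updates = {field: value}
    if field == "total_fat_g" and base.nutrients.sat_fat_g is not None:
        updates["sat_fat_g"] = min(base.nutrients.sat_fat_g, value)
    nutrients = base.nutrients.model_copy(update=updates)
    return base.model_copy(update={"nutrients": nutrients})


def generate_product(
    category: Category,
    intended_label: LabelClass,
    rs: RuleSet,
    rng: np.random.Generator,
    margin: float = 0.05,
    product_id: str = "P000000",
) -> tuple[FoodProduct, GroundTruthRecord]:
    """Draw one product constructed so the engines reproduce ``intended_label``."""
    if intended_label is LabelClass.positive:
        product = _positive_product(product_id, category, rs, rng, margin)
    elif intended_label is LabelClass.warning:
        product = _warning_product(product_id, category, rs, rng, margin)
    else:
        product = _neither_product(product_id, category, rs, rng, margin)
    truth = GroundTruthRecord(product_id=product_id, intended_label=intended_label, category=category)
    return product, truth


def generate_database(
    config: SyntheticConfig, rs: Optional[RuleSet] = None
) -> tuple[list[FoodProduct], list[GroundTruthRecord]]:
    """Generate the full synthetic table: categories drawn from the configured
    mix, intended labels from the per-category probabilities. Reproducible —
    the same config (seed included) yields identical output."""
    if rs is None:
        rs = default_ruleset()
    rng = np.random.default_rng(config.seed)
    cats = sorted(config.category_mix, key=lambda c: c.value)
    shares = np.array([config.category_mix[c] for c in cats], dtype=float)
    shares = shares / shares.sum()
    draws = rng.choice(len(cats), size=config.n_products, p=shares)

    products: list[FoodProduct] = []
    truths: list[GroundTruthRecord] = []
    for i, ci in enumerate(draws):
        category = cats[int(ci)]
        u = rng.random()
        p_pos = config.p_positive_given_category.get(category, 0.0)
        p_warn = config.p_warning_given_category.get(category, 0.0)
        if u < p_pos:
            label = LabelClass.positive
        elif u < p_pos + p_warn:
            label = LabelClass.warning
        else:
            label = LabelClass.none
        product, truth = generate_product(
            category, label, rs, rng, margin=config.margin, product_id=f"P{i:06d}"
        )
        products.append(product)
        truths.append(truth)
    return products, truths


def truth_to_records(truths: Sequence[GroundTruthRecord]) -> list[dict[str, str]]:
    return [
        {"product_id": t.product_id, "intended_label": t.intended_label.value, "category": t.category.value}
        for t in truths
    ]
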