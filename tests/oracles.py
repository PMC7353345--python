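"""Hand-written brute-force evaluators, independent of the engine code paths.

These re-derive label decisions with nothing but direct comparisons against
the criteria table and warning thresholds, and serve as the reference in the
exhaustive boundary-grid tests.
"""

from __future__ import annotations

from fopl.food_model import (
    PLANT_BASED_CATEGORIES,
    CategoryRule,
    Comparison,
    FoodProduct,
    WarningThresholds,
)

_WARN_FIELDS = ("sugars_g", "sodium_mg", "sat_fat_g")


def brute_force_warnings(product: FoodProduct, thresholds: WarningThresholds) -> set[str]:
    """Three plain comparisons; strict exceedance, missing never exceeds."""
    table = thresholds.beverages if product.is_beverage else thresholds.solids
    exceeded = set()
    for field in _WARN_FIELDS:
        value = getattr(product.nutrients, field)
        if value is not None and value > table[field]:
            exceeded.add(field)
    return exceeded


def brute_force_eligible(
    product: FoodProduct, rule: CategoryRule, thresholds: WarningThresholds
) -> bool:
    """Direct evaluation of one criteria row plus the warning-consistency
    clause: whitelist additives (water tolerated in plant foods), explicit
    limit comparisons, flag rules with unconditional enrichment ban, and no
    warning nutrient missing or above its threshold."""
    allowed = set(rule.allowed_additives)
    if product.category in PLANT_BASED_CATEGORIES:
        allowed.add("water")
    for token in product.additive_tokens:
        if token not in allowed:
            return False

    for nutrient, limit in rule.max_limits.items():
        value = getattr(product.nutrients, nutrient)
        if value is None:
            return False
        if limit.comparison is Comparison.inclusive_max and value > limit.value:
            return False
        if limit.comparison is Comparison.strict_max and value >= limit.value:
            return False

    flags = {f.value for f in product.processing_flags}
    if "enriched" in flags:
        return False
    if any(f.value in flags for f in rule.forbidden_flags):
        return False
    if any(f.value not in flags for f in rule.required_flags):
        return False

    table = thresholds.beverages if product.is_beverage else thresholds.solids
    for field in _WARN_FIELDS:
        value = getattr(product.nutrients, field)
        if value is None or value > table[field]:
            return False
    return True
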