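"""Positive ("green") endorsement-label eligibility.

Eligibility is rule-table driven: a product must match a category/subcategory
rule, carry only whitelisted additives (water is always tolerated in
plant-based foods), stay within every numeric limit at the rule's stated
comparison, satisfy the processing-flag constraints (nutritional enrichment
disqualifies unconditionally), and — the consistency clause — not exceed any
warning threshold. Mixtures are allowed only among the five plant groups
(grains, legumes, fruits, vegetables, nuts/seeds) and are judged against the
most restrictive combination of the component rules.

All checks always run (no short-circuit) so that failure-reason statistics over
a product table are unbiased.
"""

from __future__ import annotations

from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict

from .food_model import (
    PLANT_BASED_CATEGORIES,
    Category,
    CategoryRule,
    Comparison,
    FailureReason,
    FoodProduct,
    LabelClass,
    LabelDecision,
    NutrientLimit,
    ProcessingFlag,
    RuleSet,
)
from .warning_engine import evaluate_warnings


class CheckOutcome(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    passed: bool
    detail: tuple[str, ...] = ()


class EligibilityReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    product_id: str
    eligible: bool
    matched_rule: Optional[tuple[Category, str]] = None
    failure_reasons: tuple[FailureReason, ...] = ()
    checks: tuple[CheckOutcome, ...] = ()


# ---------------------------------------------------------------------------
# Individual checks
# ---------------------------------------------------------------------------


def resolve_rule(product: FoodProduct, rs: RuleSet) -> Optional[CategoryRule]:
    """Find the unique criteria row for the product's declared category and
    subcategory.

    ``other`` never matches. A product with an empty subcategory matches only
    if its category has exactly one rule. Mixtures resolve to a synthetic rule
    combining the component categories' base rules (see
    :func:`combined_mixture_rule`).
    """
    if product.category in (Category.other, Category.bread):
        return None
    if product.category is Category.mixture:
        return combined_mixture_rule(product.component_categories, rs)
    rules = rs.rules_for(product.category)
    if product.subcategory:
        for rule in rules:
            if rule.subcategory_key == product.subcategory:
                return rule
        return None
    return rules[0] if len(rules) == 1 else None


def combined_mixture_rule(components: Sequence[Category] | frozenset[Category], rs: RuleSet) -> Optional[CategoryRule]:
    """Synthesize the rule a plant-group mixture is judged against: union of
    the component base rules' additive whitelists and flag prohibitions, with
    the most restrictive numeric limit winning where components disagree."""
    components = frozenset(components)
    if not components or not components <= rs.combinable_categories:
        return None
    base_rules = []
    for cat in components:
        base = rs.mixture_base_rule(cat)
        if base is None:
            return None
        base_rules.append(base)

    allowed: frozenset[str] = frozenset().union(*(r.allowed_additives for r in base_rules))
    forbidden: frozenset[ProcessingFlag] = frozenset().union(*(r.forbidden_flags for r in base_rules))
    required: frozenset[ProcessingFlag] = frozenset().union(*(r.required_flags for r in base_rules))
    limits: dict[str, NutrientLimit] = {}
    for rule in base_rules:
        for nutrient, limit in rule.max_limits.items():
            cur = limits.get(nutrient)
            if cur is None or limit.value < cur.value or (
                limit.value == cur.value and limit.comparison is Comparison.strict_max
            ):
                limits[nutrient] = limit
    return CategoryRule(
        category=Category.mixture,
        subcategory_key="+".join(sorted(c.value for c in components)),
        allowed_additives=allowed,
        max_limits=limits,
        forbidden_flags=forbidden,
        required_flags=required,
    )


def check_additives(product: FoodProduct, rule: CategoryRule) -> CheckOutcome:
    """Whitelist semantics: every declared token must be allowed by the rule.
    Water is always tolerated in plant-based foods."""
    allowed = rule.allowed_additives
    if product.category in PLANT_BASED_CATEGORIES:
        allowed = allowed | {"water"}
    offending = product.additive_tokens - allowed
    return CheckOutcome(name="additives", passed=not offending, detail=tuple(sorted(offending)))


def check_nutrient_limits(product: FoodProduct, rule: CategoryRule) -> CheckOutcome:
    """Evaluate every numeric limit at its stated comparison; a limited
    nutrient that is not declared fails (endorsement requires evidence)."""
    detail: list[str] = []
    for nutrient, limit in sorted(rule.max_limits.items()):
        value = getattr(product.nutrients, nutrient)
        if value is None:
            detail.append(f"missing:{nutrient}")
        elif not limit.passes(value):
            op = "<=" if limit.comparison is Comparison.inclusive_max else "<"
            detail.append(f"limit:{nutrient}={value} !{op} {limit.value}")
    return CheckOutcome(name="limits", passed=not detail, detail=tuple(detail))


def check_processing_flags(product: FoodProduct, rule: CategoryRule) -> CheckOutcome:
    """Forbidden flags must be absent, required flags present; nutritional
    enrichment disqualifies every category."""
    detail: list[str] = []
    forbidden = rule.forbidden_flags | {ProcessingFlag.enriched}
    for flag in sorted(forbidden & product.processing_flags, key=lambda f: f.value):
        detail.append(f"forbidden:{flag.value}")
    for flag in sorted(rule.required_flags - product.processing_flags, key=lambda f: f.value):
        detail.append(f"required:{flag.value}")
    return CheckOutcome(name="flags", passed=not detail, detail=tuple(detail))


def check_combination(product: FoodProduct, rs: RuleSet) -> CheckOutcome:
    """Mixtures may combine only the five plant groups."""
    outside = product.component_categories - rs.combinable_categories
    detail = tuple(sorted(c.value for c in outside))
    return CheckOutcome(name="combination", passed=not outside and bool(product.component_categories), detail=detail)


def check_warning_consistency(product: FoodProduct, rs: RuleSet) -> CheckOutcome:
    """An endorsed product may not exceed any warning threshold, and every
    warning nutrient must be declared (an undeclared value cannot be certified)."""
    result = evaluate_warnings(product, rs.warning_thresholds)
    detail = tuple(
        [f"exceeded:{n.value}" for n in sorted(result.exceeded, key=lambda n: n.value)]
        + [f"indeterminate:{n.value}" for n in sorted(result.indeterminate, key=lambda n: n.value)]
    )
    return CheckOutcome(name="warning_consistency", passed=not detail, detail=detail)


# ---------------------------------------------------------------------------
# Composite classification
# ---------------------------------------------------------------------------


def classify_positive(product: FoodProduct, rs: RuleSet) -> EligibilityReport:
    """Full positive-eligibility decision with a per-check trace.

    Composes rule resolution, additive/limit/flag checks (against the matched
    rule, or the synthetic mixture rule), the combination-membership check for
    mixtures, and the warning-consistency clause. Every applicable check runs;
    the report records all failures.
    """
    checks: list[CheckOutcome] = []
    reasons: list[FailureReason] = []

    rule = resolve_rule(product, rs)
    if product.category is Category.mixture:
        combo = check_combination(product, rs)
        checks.append(combo)
        if not combo.passed:
            reasons.append(FailureReason.combination_violation)

    if rule is None:
        if product.category is not Category.mixture:
            reasons.append(FailureReason.unknown_category)
        elif not any(r.name == "combination" and not r.passed for r in checks):
            # components were combinable but some lacked a base rule
            reasons.append(FailureReason.combination_violation)
    else:
        additives = check_additives(product, rule)
        limits = check_nutrient_limits(product, rule)
        flags = check_processing_flags(product, rule)
        checks += [additives, limits, flags]
        if not additives.passed:
            reasons.append(FailureReason.additive_violation)
        if not limits.passed:
            if any(d.startswith("limit:") for d in limits.detail):
                reasons.append(FailureReason.nutrient_limit)
            if any(d.startswith("missing:") for d in limits.detail):
                reasons.append(FailureReason.missing_nutrient)
        if not flags.passed:
            reasons.append(FailureReason.processing_flag)

    consistency = check_warning_consistency(product, rs)
    checks.append(consistency)
    if not consistency.passed:
        if any(d.startswith("exceeded:") for d in consistency.detail):
            reasons.append(FailureReason.warning_conflict)
        if any(d.startswith("indeterminate:") for d in consistency.detail):
            if FailureReason.missing_nutrient not in reasons:
                reasons.append(FailureReason.missing_nutrient)

    eligible = rule is not None and not reasons
    return EligibilityReport(
        product_id=product.product_id,
        eligible=eligible,
        matched_rule=rule.key if rule is not None else None,
        failure_reasons=tuple(dict.fromkeys(reasons)),
        checks=tuple(checks),
    )


def classify_efsharibari_bread(product: FoodProduct) -> bool:
    """Legacy "Healthy is Possible" bread endorsement, pre-dating the criteria
    table: at least 80% of grain as whole grain, at most 400 mg sodium and at
    most 250 kcal per 100 g — all boundaries inclusive.

    Raises ``ValueError`` if the product is not bread or any of the three
    fields is undeclared (the decision would be indeterminate).
    """
    if product.category is not Category.bread:
        raise ValueError("EFSHARIBARI applies to bread only")
    n = product.nutrients
    if n.whole_grain_pct is None or n.sodium_mg is None or n.energy_kcal is None:
        raise ValueError("whole_grain_pct, sodium_mg and energy_kcal must all be declared")
    return n.whole_grain_pct >= 80 and n.sodium_mg <= 400 and n.energy_kcal <= 250


def label_product(product: FoodProduct, rs: RuleSet) -> LabelDecision:
    """Three-way label decision: positive, warning (1-3 marks), or neither."""
    report = classify_positive(product, rs)
    warning = evaluate_warnings(product, rs.warning_thresholds)
    label = (
        LabelClass.positive
        if report.eligible
        else LabelClass.warning
        if warning.exceeded
        else LabelClass.none
    )
    return LabelDecision(
        product_id=product.product_id,
        positive_eligible=report.eligible,
        positive_failure_reasons=report.failure_reasons,
        warnings=warning.exceeded,
        label_class=label,
    )


def label_products(products: Sequence[FoodProduct], rs: RuleSet) -> list[LabelDecision]:
    return [label_product(p, rs) for p in products]
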