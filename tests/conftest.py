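from __future__ import annotations

import itertools

import pytest

from fopl.food_model import (
    Category,
    CategoryRule,
    FoodProduct,
    NutrientProfile,
    ProcessingFlag,
    RuleSet,
    Stage,
    default_ruleset,
    thresholds_for_stage,
)

_ids = itertools.count()


@pytest.fixture(scope="session")
def ruleset() -> RuleSet:
    return default_ruleset()


@pytest.fixture(scope="session")
def stage1():
    return thresholds_for_stage(Stage.stage1_2020)


@pytest.fixture(scope="session")
def stage2():
    return thresholds_for_stage(Stage.stage2_2021)


def make_product(
    category: Category = Category.other,
    subcategory: str = "",
    additives: set[str] = frozenset(),
    flags: set[ProcessingFlag] = frozenset(),
    components: set[Category] = frozenset(),
    is_beverage: bool = False,
    name: str = "",
    **nutrients: float,
) -> FoodProduct:
    """Terse product factory for tests; nutrient kwargs are profile fields."""
    return FoodProduct(
        product_id=f"T{next(_ids):05d}",
        name=name or f"test {category.value}",
        category=category,
        subcategory=subcategory,
        is_beverage=is_beverage,
        nutrients=NutrientProfile(**nutrients),
        additive_tokens=frozenset(additives),
        processing_flags=frozenset(flags),
        component_categories=frozenset(components),
    )


def boundary_grid(rule: CategoryRule, eps: float = 0.01):
    """Exhaustive boundary grid for one criteria row: every limit at its value
    and value*(1 +/- eps), every whitelist token (plus one forbidden token)
    present/absent, every forbidden flag on/off, required flags on/off, and
    the unconditional enrichment flag on/off. Yields FoodProducts declaring
    the rule's category/subcategory, with warning nutrients low unless they
    are themselves limited."""
    limit_axes = []
    for nutrient, limit in sorted(rule.max_limits.items()):
        vals = [limit.value * (1 - eps), limit.value, limit.value * (1 + eps)]
        limit_axes.append([(nutrient, v) for v in vals])

    tokens = sorted(rule.allowed_additives) + ["preservative"]
    token_axes = [[(), (t,)] for t in tokens]

    flag_pool = sorted(rule.forbidden_flags | rule.required_flags | {ProcessingFlag.enriched},
                       key=lambda f: f.value)
    flag_axes = [[(), (f,)] for f in flag_pool]

    for combo in itertools.product(*limit_axes, *token_axes, *flag_axes):
        nutrients: dict[str, float] = {}
        additives: set[str] = set()
        flags: set[ProcessingFlag] = set()
        for part in combo:
            if not part:
                continue
            if len(part) == 2:
                nutrients[part[0]] = part[1]
            elif isinstance(part[0], ProcessingFlag):
                flags.add(part[0])
            else:
                additives.add(part[0])
        # declare warning nutrients not already pinned by a limit
        nutrients.setdefault("sugars_g", 1.0)
        nutrients.setdefault("sodium_mg", 10.0)
        nutrients.setdefault("sat_fat_g", 0.5)
        nutrients.setdefault("total_fat_g", max(1.0, nutrients.get("total_fat_g", 0.0), nutrients["sat_fat_g"]))
        yield make_product(
            category=rule.category,
            subcategory=rule.subcategory_key,
            additives=additives,
            flags=flags,
            is_beverage=rule.is_beverage,
            **nutrients,
        )
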