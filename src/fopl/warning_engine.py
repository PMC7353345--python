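"""Mandatory warning ("red") label computation.

A product carries one warning mark per regulated nutrient — sugar, sodium,
saturated fat — whose declared amount *strictly exceeds* the stage threshold on
the applicable basis (per 100 g for solids, per 100 mL for beverages). Energy
never triggers a warning. A missing value is *indeterminate*: it never counts
as exceeded, but downstream positive eligibility refuses to certify it.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, model_validator

from .food_model import (
    WARNING_NUTRIENT_FIELDS,
    FoodProduct,
    Stage,
    WarningNutrient,
    WarningThresholds,
)


class WarningResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    product_id: str
    exceeded: frozenset[WarningNutrient] = frozenset()
    stage: Stage
    basis: str  # "solids" | "beverages"
    indeterminate: frozenset[WarningNutrient] = frozenset()

    @model_validator(mode="after")
    def _disjoint(self) -> "WarningResult":
        if self.exceeded & self.indeterminate:
            raise ValueError("a nutrient cannot be both exceeded and indeterminate")
        return self


def evaluate_warnings(product: FoodProduct, thresholds: WarningThresholds) -> WarningResult:
    """Compare the product's sugar, sodium and saturated fat against the stage
    thresholds; strict exceedance triggers the warning, ties do not."""
    table = thresholds.basis_for(product.is_beverage)
    exceeded: set[WarningNutrient] = set()
    indeterminate: set[WarningNutrient] = set()
    for nutrient, field in WARNING_NUTRIENT_FIELDS.items():
        value = getattr(product.nutrients, field)
        if value is None:
            indeterminate.add(nutrient)
        elif value > table[field]:
            exceeded.add(nutrient)
    return WarningResult(
        product_id=product.product_id,
        exceeded=frozenset(exceeded),
        stage=thresholds.stage,
        basis="beverages" if product.is_beverage else "solids",
        indeterminate=frozenset(indeterminate),
    )


def count_warnings(result: WarningResult) -> int:
    """Number of warning marks the product must carry (0-3)."""
    return len(result.exceeded)
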