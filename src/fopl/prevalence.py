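"""Label-prevalence summaries over a classified product table.

Reports the share of products carrying each label class overall, the food-group
composition of the positive-eligible set, and within-group label rates, using
the reporting groups of the published national analysis: milk & dairy; meat,
poultry, fish & egg; grains; legumes; fruits & vegetables (merged); other.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .food_model import Category, FoodProduct, LabelClass, LabelDecision

MILK_DAIRY = "milk_dairy"
MEAT_FISH_EGG = "meat_fish_egg"
GRAINS = "grains"
LEGUMES = "legumes"
FRUITS_VEGETABLES = "fruits_vegetables"
OTHER = "other"

REPORTING_GROUPS = (MILK_DAIRY, MEAT_FISH_EGG, GRAINS, LEGUMES, FRUITS_VEGETABLES, OTHER)

#: Category -> reporting group. Eggs are merged into the meat/poultry/fish
#: group and fruits with vegetables, matching the published breakdown; soy,
#: oils, nuts, tahini, tea, bread and mixtures fall under "other".
REPORTING_GROUP_OF: Mapping[Category, str] = {
    Category.dairy: MILK_DAIRY,
    Category.eggs: MEAT_FISH_EGG,
    Category.fish: MEAT_FISH_EGG,
    Category.poultry: MEAT_FISH_EGG,
    Category.grains: GRAINS,
    Category.legumes: LEGUMES,
    Category.fruits: FRUITS_VEGETABLES,
    Category.vegetables: FRUITS_VEGETABLES,
}


def reporting_group(category: Category) -> str:
    return REPORTING_GROUP_OF.get(category, OTHER)


class PrevalenceSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_total: int
    pct_positive: float
    pct_warning: float
    pct_none: float
    positive_composition: Mapping[str, float]  # group -> % of positive-eligible products
    within_group: Mapping[str, tuple[float, float, float]]  # group -> (pos, warn, none) %

    @model_validator(mode="after")
    def _sums(self) -> "PrevalenceSummary":
        if self.n_total:
            if abs(self.pct_positive + self.pct_warning + self.pct_none - 100.0) > 1e-6:
                raise ValueError("overall percentages must sum to 100")
            comp_total = sum(self.positive_composition.values())
            if self.positive_composition and abs(comp_total - 100.0) > 1e-6:
                raise ValueError("positive composition must sum to 100")
            for group, triple in self.within_group.items():
                if abs(sum(triple) - 100.0) > 1e-6:
                    raise ValueError(f"within-group percentages for {group} must sum to 100")
        return self


def summarize_prevalence(
    decisions: Sequence[LabelDecision], products: Sequence[FoodProduct]
) -> PrevalenceSummary:
    """Straight product-count proportions of the three label classes, overall
    and per reporting group, plus the group composition of the positive set.

    Percentages are unrounded; round only at presentation. Raises if a decision
    has no matching product.
    """
    by_id = {p.product_id: p for p in products}
    missing = [d.product_id for d in decisions if d.product_id not in by_id]
    if missing:
        raise ValueError(f"decisions without matching product: {missing[:5]}")

    n = len(decisions)
    if n == 0:
        return PrevalenceSummary(
            n_total=0, pct_positive=0.0, pct_warning=0.0, pct_none=0.0,
            positive_composition={}, within_group={},
        )

    frame = pd.DataFrame(
        {
            "label": [d.label_class.value for d in decisions],
            "group": [reporting_group(by_id[d.product_id].category) for d in decisions],
        }
    )
    counts = frame["label"].value_counts()
    pct = {lab: 100.0 * counts.get(lab, 0) / n for lab in ("positive", "warning", "none")}

    positive = frame[frame["label"] == "positive"]
    composition: dict[str, float] = {}
    if len(positive):
        comp_counts = positive["group"].value_counts()
        composition = {g: 100.0 * comp_counts.get(g, 0) / len(positive) for g in REPORTING_GROUPS}

    within: dict[str, tuple[float, float, float]] = {}
    for group, sub in frame.groupby("group"):
        gcounts = sub["label"].value_counts()
        gn = len(sub)
        within[str(group)] = tuple(100.0 * gcounts.get(lab, 0) / gn for lab in ("positive", "warning", "none"))

    return PrevalenceSummary(
        n_total=n,
        pct_positive=pct["positive"],
        pct_warning=pct["warning"],
        pct_none=pct["none"],
        positive_composition=composition,
        within_group=within,
    )


#: Published national-analysis reference values, as flat metric paths (%).
PUBLISHED_REFERENCE: Mapping[str, float] = {
    "pct_positive": 19.8,
    "pct_warning": 14.1,
    f"positive_composition.{FRUITS_VEGETABLES}": 54.0,
    f"positive_composition.{MILK_DAIRY}": 20.0,
    f"positive_composition.{GRAINS}": 14.0,
    f"positive_composition.{MEAT_FISH_EGG}": 11.0,
    f"positive_composition.{LEGUMES}": 1.0,
    f"within_group.{MILK_DAIRY}.pct_positive": 57.2,
    f"within_group.{MEAT_FISH_EGG}.pct_positive": 37.8,
    f"within_group.{GRAINS}.pct_positive": 32.0,
}


def summary_metrics(summary: PrevalenceSummary) -> dict[str, float]:
    """Flatten a summary into the metric paths used by the published reference."""
    metrics: dict[str, float] = {
        "pct_positive": summary.pct_positive,
        "pct_warning": summary.pct_warning,
        "pct_none": summary.pct_none,
    }
    for group, share in summary.positive_composition.items():
        metrics[f"positive_composition.{group}"] = share
    for group, (pos, warn, none) in summary.within_group.items():
        metrics[f"within_group.{group}.pct_positive"] = pos
        metrics[f"within_group.{group}.pct_warning"] = warn
        metrics[f"within_group.{group}.pct_none"] = none
    return metrics


def compare_to_published(
    summary: PrevalenceSummary, reference: Optional[Mapping[str, float]] = None
) -> pd.DataFrame:
    """Tabulate observed vs reference percentages with absolute deviations.

    Metrics absent from the observed summary are kept but marked
    non-comparable (NaN deviation).
    """
    reference = PUBLISHED_REFERENCE if reference is None else reference
    observed = summary_metrics(summary)
    rows = []
    for metric, ref in reference.items():
        obs = observed.get(metric)
        rows.append(
            {
                "metric": metric,
                "observed": obs,
                "reference": ref,
                "abs_deviation": abs(obs - ref) if obs is not None else float("nan"),
                "comparable": obs is not None,
            }
        )
    return pd.DataFrame(rows, columns=["metric", "observed", "reference", "abs_deviation", "comparable"])
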