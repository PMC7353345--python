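"""Domain types and I/O for the Israeli dual front-of-package labeling (FOPL) system.

The Israeli system pairs a mandatory warning ("red") label — one mark each for
sugar, sodium and saturated fat above a regulatory threshold — with a voluntary
positive ("green") endorsement label granted only to foods in their natural form
or minimally processed, with no food additives, under category-specific criteria.

This module defines the in-memory model (products, nutrient profiles, rule sets,
label decisions) and readers/writers for product tables (CSV/JSON) and rule-set
files (YAML). Rule *content* — the category criteria and warning thresholds —
lives in bundled data files under :mod:`fopl.rulesets`, not in code.
"""

from __future__ import annotations

import json
import logging
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

logger = logging.getLogger("fopl")

#: mg sodium per g of salt (NaCl): molar-mass ratio 22.99/58.44, per mille.
SODIUM_MG_PER_G_SALT = 393.4


class Category(str, Enum):
    """Declared food category. ``other`` is never positive-eligible; ``mixture``
    is the sentinel for multi-category products (see ``component_categories``)."""

    dairy = "dairy"
    soy = "soy"
    vegetable_oil = "vegetable_oil"
    seeds_nuts = "seeds_nuts"
    grains = "grains"
    legumes = "legumes"
    tahini = "tahini"
    eggs = "eggs"
    fish = "fish"
    poultry = "poultry"
    fruits = "fruits"
    vegetables = "vegetables"
    tea = "tea"
    bread = "bread"
    other = "other"
    mixture = "mixture"


#: Categories for which water never counts as an additive.
PLANT_BASED_CATEGORIES = frozenset(
    {
        Category.soy,
        Category.vegetable_oil,
        Category.seeds_nuts,
        Category.grains,
        Category.legumes,
        Category.tahini,
        Category.fruits,
        Category.vegetables,
        Category.tea,
        Category.mixture,
    }
)


class ProcessingFlag(str, Enum):
    fried = "fried"
    juiced = "juiced"
    dried = "dried"
    freeze_dried_reconstituted = "freeze_dried_reconstituted"
    sweetened = "sweetened"
    enriched = "enriched"
    fresh_raw = "fresh_raw"
    canned = "canned"


class WarningNutrient(str, Enum):
    sugar = "sugar"
    sodium = "sodium"
    sat_fat = "sat_fat"


#: Warning nutrient -> NutrientProfile field holding its per-100 g/mL amount.
WARNING_NUTRIENT_FIELDS: Mapping[WarningNutrient, str] = {
    WarningNutrient.sugar: "sugars_g",
    WarningNutrient.sodium: "sodium_mg",
    WarningNutrient.sat_fat: "sat_fat_g",
}


class Comparison(str, Enum):
    inclusive_max = "inclusive_max"  # value <= limit passes ("<=" in the criteria table)
    strict_max = "strict_max"  # value < limit passes ("<" in the criteria table)


class Stage(str, Enum):
    stage1_2020 = "stage1_2020"
    stage2_2021 = "stage2_2021"


class LabelClass(str, Enum):
    positive = "positive"
    warning = "warning"
    none = "none"


class FailureReason(str, Enum):
    unknown_category = "unknown_category"
    additive_violation = "additive_violation"
    nutrient_limit = "nutrient_limit"
    processing_flag = "processing_flag"
    combination_violation = "combination_violation"
    warning_conflict = "warning_conflict"
    missing_nutrient = "missing_nutrient"


class NutrientProfile(BaseModel):
    """Per-100 g (or per-100 mL for beverages) nutrient declaration.

    ``None`` means *not declared* — never zero. Positive eligibility requires
    every limited nutrient to be declared; warnings treat a missing value as
    indeterminate rather than compliant.
    """

    model_config = ConfigDict(frozen=True)

    energy_kcal: Optional[float] = Field(None, ge=0)
    total_fat_g: Optional[float] = Field(None, ge=0)
    sat_fat_g: Optional[float] = Field(None, ge=0)
    sugars_g: Optional[float] = Field(None, ge=0)
    sodium_mg: Optional[float] = Field(None, ge=0)
    whole_grain_pct: Optional[float] = Field(None, ge=0, le=100)
    calcium_mg: Optional[float] = Field(None, ge=0)  # reserved, no rule uses it yet

    @model_validator(mode="after")
    def _sat_fat_within_total(self) -> "NutrientProfile":
        if self.sat_fat_g is not None and self.total_fat_g is not None:
            if self.sat_fat_g > self.total_fat_g:
                raise ValueError("sat_fat_g exceeds total_fat_g")
        return self


class FoodProduct(BaseModel):
    model_config = ConfigDict(frozen=True)

    product_id: str
    name: str = ""
    category: Category
    subcategory: str = ""
    is_beverage: bool = False
    nutrients: NutrientProfile = NutrientProfile()
    additive_tokens: frozenset[str] = frozenset()
    processing_flags: frozenset[ProcessingFlag] = frozenset()
    component_categories: frozenset[Category] = frozenset()

    @field_validator("additive_tokens", mode="before")
    @classmethod
    def _normalize_tokens(cls, v: Iterable[str]) -> frozenset[str]:
        return frozenset(t.strip().lower() for t in v if str(t).strip())

    @model_validator(mode="after")
    def _mixture_sentinel(self) -> "FoodProduct":
        if self.component_categories and self.category is not Category.mixture:
            raise ValueError("component_categories set requires category 'mixture'")
        if self.category is Category.mixture and not self.component_categories:
            raise ValueError("category 'mixture' requires nonempty component_categories")
        return self


class NutrientLimit(BaseModel):
    model_config = ConfigDict(frozen=True)

    value: float = Field(ge=0)
    comparison: Comparison

    def passes(self, amount: float) -> bool:
        if self.comparison is Comparison.inclusive_max:
            return amount <= self.value
        return amount < self.value


class CategoryRule(BaseModel):
    """One row of the positive-label criteria table: an additive whitelist,
    numeric maxima with explicit comparison kind, and processing-flag rules."""

    model_config = ConfigDict(frozen=True)

    category: Category
    subcategory_key: str
    allowed_additives: frozenset[str] = frozenset()
    max_limits: Mapping[str, NutrientLimit] = {}
    forbidden_flags: frozenset[ProcessingFlag] = frozenset()
    required_flags: frozenset[ProcessingFlag] = frozenset()
    is_beverage: bool = False
    mixture_base: bool = False  # representative rule used for combination products

    @field_validator("allowed_additives", mode="before")
    @classmethod
    def _lower(cls, v: Iterable[str]) -> frozenset[str]:
        return frozenset(t.strip().lower() for t in v)

    @property
    def key(self) -> tuple[Category, str]:
        return (self.category, self.subcategory_key)


class WarningThresholds(BaseModel):
    """Regulatory exceedance thresholds for one stage: per 100 g for solids,
    per 100 mL for beverages. A warning fires on *strict* exceedance."""

    model_config = ConfigDict(frozen=True)

    stage: Stage
    solids: Mapping[str, float]
    beverages: Mapping[str, float]

    @field_validator("solids", "beverages")
    @classmethod
    def _complete_and_nonneg(cls, v: Mapping[str, float]) -> Mapping[str, float]:
        required = set(WARNING_NUTRIENT_FIELDS.values())
        if set(v) != required:
            raise ValueError(f"threshold mapping must have exactly keys {sorted(required)}")
        if any(x < 0 for x in v.values()):
            raise ValueError("thresholds must be nonnegative")
        return dict(v)

    def basis_for(self, is_beverage: bool) -> Mapping[str, float]:
        return self.beverages if is_beverage else self.solids


DEFAULT_COMBINABLE = frozenset(
    {Category.grains, Category.legumes, Category.fruits, Category.vegetables, Category.seeds_nuts}
)


class RuleSet(BaseModel):
    model_config = ConfigDict(frozen=True)

    category_rules: tuple[CategoryRule, ...]
    warning_thresholds: WarningThresholds
    combinable_categories: frozenset[Category] = DEFAULT_COMBINABLE
    version: str = "unversioned"

    @model_validator(mode="after")
    def _unique_keys(self) -> "RuleSet":
        keys = [r.key for r in self.category_rules]
        if len(keys) != len(set(keys)):
            dupes = sorted({f"{c.value}/{s}" for c, s in keys if keys.count((c, s)) > 1})
            raise ValueError(f"duplicate (category, subcategory) rule keys: {dupes}")
        return self

    def rules_for(self, category: Category) -> list[CategoryRule]:
        return [r for r in self.category_rules if r.category is category]

    def mixture_base_rule(self, category: Category) -> Optional[CategoryRule]:
        for r in self.category_rules:
            if r.category is category and r.mixture_base:
                return r
        return None


class LabelDecision(BaseModel):
    """Final three-way outcome for one product. Positive and warning labels are
    mutually exclusive; a product may also carry neither — the absence of a
    warning label does not make a product endorsable."""

    model_config = ConfigDict(frozen=True)

    product_id: str
    positive_eligible: bool
    positive_failure_reasons: tuple[FailureReason, ...] = ()
    warnings: frozenset[WarningNutrient] = frozenset()
    label_class: LabelClass

    @model_validator(mode="after")
    def _exclusive(self) -> "LabelDecision":
        if self.positive_eligible and self.warnings:
            raise ValueError("positive and warning labels cannot co-occur")
        expected = (
            LabelClass.positive
            if self.positive_eligible
            else LabelClass.warning
            if self.warnings
            else LabelClass.none
        )
        if self.label_class is not expected:
            raise ValueError(f"label_class {self.label_class} inconsistent (expected {expected})")
        return self


class ValidationIssue(BaseModel):
    model_config = ConfigDict(frozen=True)

    code: str
    detail: str


# ---------------------------------------------------------------------------
# Product-table I/O
# ---------------------------------------------------------------------------

PRODUCT_COLUMNS = [
    "product_id",
    "name",
    "category",
    "subcategory",
    "is_beverage",
    "energy_kcal",
    "total_fat_g",
    "sat_fat_g",
    "sugars_g",
    "sodium_mg",
    "whole_grain_pct",
    "additives",
    "flags",
    "components",
]

_NUTRIENT_COLS = ["energy_kcal", "total_fat_g", "sat_fat_g", "sugars_g", "sodium_mg", "whole_grain_pct"]


def _split_tokens(cell: object) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return []
    return [t.strip() for t in str(cell).split(";") if t.strip()]


def _record_to_product(rec: Mapping[str, object]) -> FoodProduct:
    nutrients = {}
    for col in _NUTRIENT_COLS:
        raw = rec.get(col)
        if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
            continue  # absent, never zero
        val = float(raw)
        if val < 0:
            raise ValueError(f"negative nutrient {col}={val}")
        nutrients[col] = val
    is_bev = rec.get("is_beverage", False)
    if isinstance(is_bev, str):
        is_bev = is_bev.strip().lower() in {"1", "true", "yes"}
    return FoodProduct(
        product_id=str(rec["product_id"]),
        name=str(rec.get("name") or ""),
        category=Category(str(rec["category"]).strip().lower()),
        subcategory=str(rec.get("subcategory") or "").strip()
        if not (isinstance(rec.get("subcategory"), float) and pd.isna(rec.get("subcategory")))
        else "",
        is_beverage=bool(is_bev),
        nutrients=NutrientProfile(**nutrients),
        additive_tokens=frozenset(_split_tokens(rec.get("additives"))),
        processing_flags=frozenset(ProcessingFlag(f) for f in _split_tokens(rec.get("flags"))),
        component_categories=frozenset(Category(c) for c in _split_tokens(rec.get("components"))),
    )


def load_food_table(path: str | Path, format: str | None = None, strict: bool = False) -> list[FoodProduct]:
    """Read a product table (CSV or JSON array of objects) into ``FoodProduct``s.

    Missing nutrient cells become absent (``None``), never zero. Records with an
    unknown category or a negative nutrient are rejected: logged and skipped, or
    fatal when ``strict`` is set.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        frame = frame.replace({"": None})
        records: Sequence[Mapping[str, object]] = frame.to_dict(orient="records")
    elif fmt == "json":
        records = json.loads(path.read_text())
    else:
        raise ValueError(f"unknown format {fmt!r}")

    products: list[FoodProduct] = []
    for i, rec in enumerate(records):
        try:
            products.append(_record_to_product(rec))
        except (ValueError, KeyError) as exc:
            msg = f"rejecting record {i} ({rec.get('product_id', '?')}): {exc}"
            if strict:
                raise ValueError(msg) from exc
            logger.error(msg)
    return products


def product_to_record(p: FoodProduct) -> dict[str, object]:
    rec: dict[str, object] = {
        "product_id": p.product_id,
        "name": p.name,
        "category": p.category.value,
        "subcategory": p.subcategory,
        "is_beverage": p.is_beverage,
    }
    for col in _NUTRIENT_COLS:
        rec[col] = getattr(p.nutrients, col)
    rec["additives"] = ";".join(sorted(p.additive_tokens))
    rec["flags"] = ";".join(sorted(f.value for f in p.processing_flags))
    rec["components"] = ";".join(sorted(c.value for c in p.component_categories))
    return rec


def write_food_table(products: Sequence[FoodProduct], path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    records = [product_to_record(p) for p in products]
    if fmt == "csv":
        pd.DataFrame(records, columns=PRODUCT_COLUMNS).to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(records, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Label-decision I/O (lossless round trip)
# ---------------------------------------------------------------------------


def write_label_results(decisions: Sequence[LabelDecision], path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    records = [
        {
            "product_id": d.product_id,
            "positive_eligible": d.positive_eligible,
            "positive_failure_reasons": ";".join(r.value for r in d.positive_failure_reasons),
            "warnings": ";".join(sorted(w.value for w in d.warnings)),
            "label_class": d.label_class.value,
        }
        for d in decisions  # pydantic has already enforced the exclusivity invariant
    ]
    if fmt == "csv":
        pd.DataFrame(
            records,
            columns=["product_id", "positive_eligible", "positive_failure_reasons", "warnings", "label_class"],
        ).to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(records, indent=1))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_label_results(path: str | Path, format: str | None = None) -> list[LabelDecision]:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        records = frame.to_dict(orient="records")
    else:
        records = json.loads(path.read_text())
    out = []
    for rec in records:
        eligible = rec["positive_eligible"]
        if isinstance(eligible, str):
            eligible = eligible.strip().lower() in {"1", "true", "yes"}
        out.append(
            LabelDecision(
                product_id=str(rec["product_id"]),
                positive_eligible=bool(eligible),
                positive_failure_reasons=tuple(
                    FailureReason(t) for t in _split_tokens(rec.get("positive_failure_reasons"))
                ),
                warnings=frozenset(WarningNutrient(t) for t in _split_tokens(rec.get("warnings"))),
                label_class=LabelClass(str(rec["label_class"])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Rule-set I/O
# ---------------------------------------------------------------------------

BUNDLED_RULESETS = {"israeli_positive_v1"}
BUNDLED_THRESHOLDS = {"israeli_warning_stage1": Stage.stage1_2020, "israeli_warning_stage2": Stage.stage2_2021}


def _bundled_text(name: str) -> str:
    return resources.files("fopl.rulesets").joinpath(f"{name}.yaml").read_text()


def _ruleset_text(name_or_path: str | Path) -> str:
    name = str(name_or_path)
    if name in BUNDLED_RULESETS or name in BUNDLED_THRESHOLDS:
        return _bundled_text(name)
    return Path(name_or_path).read_text()


def load_warning_thresholds(name_or_path: str | Path) -> WarningThresholds:
    """Load a warning-threshold file, bundled (``israeli_warning_stage1``/``2``)
    or user-supplied."""
    doc = yaml.safe_load(_ruleset_text(name_or_path))
    return WarningThresholds(stage=Stage(doc["stage"]), solids=doc["solids"], beverages=doc["beverages"])


def thresholds_for_stage(stage: Stage | str) -> WarningThresholds:
    stage = Stage(stage)
    name = {Stage.stage1_2020: "israeli_warning_stage1", Stage.stage2_2021: "israeli_warning_stage2"}[stage]
    return load_warning_thresholds(name)


def _parse_rule(doc: Mapping[str, object]) -> CategoryRule:
    limits = {}
    for nutrient, spec in (doc.get("limits") or {}).items():
        if not isinstance(spec, Mapping) or "value" not in spec or "comparison" not in spec:
            raise ValueError(f"limit for {nutrient!r} must state value and comparison explicitly")
        limits[nutrient] = NutrientLimit(value=float(spec["value"]), comparison=Comparison(spec["comparison"]))
    return CategoryRule(
        category=Category(doc["category"]),
        subcategory_key=str(doc["subcategory"]),
        allowed_additives=frozenset(doc.get("allowed_additives") or []),
        max_limits=limits,
        forbidden_flags=frozenset(ProcessingFlag(f) for f in (doc.get("forbidden_flags") or [])),
        required_flags=frozenset(ProcessingFlag(f) for f in (doc.get("required_flags") or [])),
        is_beverage=bool(doc.get("beverage", False)),
        mixture_base=bool(doc.get("mixture_base", False)),
    )


def load_ruleset(name_or_path: str | Path, warning: str | Path | Stage | None = None) -> RuleSet:
    """Load a positive-criteria rule set (bundled ``israeli_positive_v1`` or a
    user file), resolving its warning-threshold reference.

    ``warning`` overrides the file's ``warning_thresholds`` reference — pass a
    stage, a bundled name, or a path.
    """
    doc = yaml.safe_load(_ruleset_text(name_or_path))
    rules = tuple(_parse_rule(r) for r in doc["rules"])
    if warning is None:
        warning = doc.get("warning_thresholds", "israeli_warning_stage1")
    if isinstance(warning, Stage) or str(warning) in {s.value for s in Stage}:
        thresholds = thresholds_for_stage(Stage(warning))
    else:
        thresholds = load_warning_thresholds(warning)
    combinable = frozenset(Category(c) for c in doc.get("combinable_categories", [c.value for c in DEFAULT_COMBINABLE]))
    return RuleSet(
        category_rules=rules,
        warning_thresholds=thresholds,
        combinable_categories=combinable,
        version=str(doc.get("version", "unversioned")),
    )


def default_ruleset(stage: Stage | str = Stage.stage1_2020) -> RuleSet:
    """The bundled Israeli positive-criteria rules with the given warning stage."""
    return load_ruleset("israeli_positive_v1", warning=Stage(stage))


def validate_ruleset(rs: RuleSet, stage1_reference: WarningThresholds | None = None) -> list[ValidationIssue]:
    """Report rule-set consistency issues as machine-readable codes.

    Returns an empty list iff the rule set is internally consistent. When the
    rule set carries stage-2 thresholds, pass the stage-1 table to check that
    the second stage is strictly no looser (``stage_monotonicity``).
    """
    issues: list[ValidationIssue] = []

    non_plant = rs.combinable_categories - DEFAULT_COMBINABLE
    for cat in sorted(c.value for c in non_plant):
        issues.append(
            ValidationIssue(
                code="non_plant_combinable",
                detail=f"category {cat!r} is not one of the five combinable plant groups",
            )
        )

    for cat in sorted(rs.combinable_categories, key=lambda c: c.value):
        if cat in DEFAULT_COMBINABLE and rs.mixture_base_rule(cat) is None and rs.rules_for(cat):
            issues.append(
                ValidationIssue(
                    code="no_mixture_base",
                    detail=f"combinable category {cat.value!r} has no mixture_base rule",
                )
            )

    if stage1_reference is not None and rs.warning_thresholds.stage is Stage.stage2_2021:
        for basis in ("solids", "beverages"):
            t2 = getattr(rs.warning_thresholds, basis)
            t1 = getattr(stage1_reference, basis)
            for nutrient in t2:
                if t2[nutrient] > t1[nutrient]:
                    issues.append(
                        ValidationIssue(
                            code="stage_monotonicity",
                            detail=f"stage-2 {basis} threshold for {nutrient} ({t2[nutrient]}) "
                            f"exceeds stage-1 ({t1[nutrient]})",
                        )
                    )
    return issues


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def sodium_from_salt(salt_g: float) -> float:
    """Convert declared salt (NaCl, g) to sodium (mg): sodium is 22.99/58.44 of
    salt by mass, i.e. 393.4 mg per gram of salt."""
    if salt_g < 0:
        raise ValueError("salt_g must be nonnegative")
    return salt_g * SODIUM_MG_PER_G_SALT
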