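"""Positive ("green") eligibility: worked criteria rows, mixtures, the
warning-consistency clause, the legacy bread label, and the exhaustive
boundary-grid comparison against the hand-written oracle."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fopl.food_model import Category, FailureReason, ProcessingFlag
from fopl.positive_engine import (
    check_additives,
    check_combination,
    check_nutrient_limits,
    check_processing_flags,
    check_warning_consistency,
    classify_efsharibari_bread,
    classify_positive,
    combined_mixture_rule,
    label_product,
    resolve_rule,
)
from fopl.warning_engine import evaluate_warnings

from conftest import boundary_grid, make_product
from oracles import brute_force_eligible


def rule_for(ruleset, subcategory):
    (rule,) = [r for r in ruleset.category_rules if r.subcategory_key == subcategory]
    return rule


class TestRuleResolution:
    def test_declared_subcategory_matches(self, ruleset):
        product = make_product(Category.dairy, subcategory="cheeses")
        assert resolve_rule(product, ruleset).subcategory_key == "cheeses"

    def test_other_category_never_matches(self, ruleset):
        assert resolve_rule(make_product(Category.other), ruleset) is None

    def test_empty_subcategory_resolves_only_when_unambiguous(self, ruleset):
        assert resolve_rule(make_product(Category.fruits), ruleset) is not None
        assert resolve_rule(make_product(Category.dairy), ruleset) is None  # three dairy rules


class TestWorkedRows:
    def test_plain_yogurt_is_eligible(self, ruleset):
        yogurt = make_product(Category.dairy, subcategory="fermented_milk",
                              total_fat_g=4.5, sat_fat_g=3.0, sugars_g=4.5, sodium_mg=50)
        report = classify_positive(yogurt, ruleset)
        assert report.eligible and report.failure_reasons == ()

    def test_sweetened_yogurt_is_not(self, ruleset):
        yogurt = make_product(Category.dairy, subcategory="fermented_milk",
                              additives={"sweetener"},
                              total_fat_g=4.5, sat_fat_g=3.0, sugars_g=4.5, sodium_mg=50)
        report = classify_positive(yogurt, ruleset)
        assert not report.eligible
        assert report.failure_reasons == (FailureReason.additive_violation,)

    def test_cheese_at_inclusive_boundaries_is_eligible(self, ruleset):
        cheese = make_product(Category.dairy, subcategory="cheeses", additives={"salt", "spice"},
                              total_fat_g=5.0, sat_fat_g=3.5, sugars_g=1.0, sodium_mg=200.0)
        assert classify_positive(cheese, ruleset).eligible

    def test_legume_spread_at_exactly_7g_fat_fails_strict_limit(self, ruleset):
        spread = make_product(Category.legumes, subcategory="legume_spreads",
                              additives={"tahini", "olive_oil", "lemon"},
                              total_fat_g=7.0, sat_fat_g=1.0, sugars_g=2.0, sodium_mg=150)
        report = classify_positive(spread, ruleset)
        assert not report.eligible
        assert FailureReason.nutrient_limit in report.failure_reasons

    @pytest.mark.parametrize("sodium,eligible", [(300.0, True), (300.1, False)])
    def test_raw_poultry_sodium_boundary(self, ruleset, sodium, eligible):
        bird = make_product(Category.poultry, subcategory="fresh_raw",
                            flags={ProcessingFlag.fresh_raw},
                            total_fat_g=8.0, sat_fat_g=2.5, sugars_g=0.0, sodium_mg=sodium)
        assert classify_positive(bird, ruleset).eligible is eligible

    def test_fruit_juice_fails_on_processing_flag(self, ruleset):
        juice = make_product(Category.fruits, flags={ProcessingFlag.juiced},
                             total_fat_g=0.2, sat_fat_g=0.0, sugars_g=10.0, sodium_mg=5,
                             is_beverage=False)
        report = classify_positive(juice, ruleset)
        assert not report.eligible
        assert FailureReason.processing_flag in report.failure_reasons

    def test_reconstituted_freeze_dried_fruit_passes_flags(self, ruleset):
        fruit = make_product(Category.fruits, flags={ProcessingFlag.freeze_dried_reconstituted},
                             total_fat_g=0.5, sat_fat_g=0.1, sugars_g=9.0, sodium_mg=3)
        assert classify_positive(fruit, ruleset).eligible

    def test_olive_oil_with_antioxidant_additives_passes(self, ruleset):
        oil = make_product(Category.vegetable_oil, additives={"tocopherol", "ascorbic_acid"},
                           total_fat_g=100.0, sat_fat_g=4.9, sugars_g=0.0, sodium_mg=0.0)
        assert classify_positive(oil, ruleset).eligible

    def test_egg_without_fresh_raw_flag_fails(self, ruleset):
        egg = make_product(Category.eggs, total_fat_g=9.5, sat_fat_g=3.1, sugars_g=0.4, sodium_mg=140)
        report = classify_positive(egg, ruleset)
        assert not report.eligible
        assert FailureReason.processing_flag in report.failure_reasons

    def test_enrichment_disqualifies_any_category(self, ruleset):
        fruit = make_product(Category.fruits, flags={ProcessingFlag.enriched},
                             total_fat_g=0.5, sat_fat_g=0.1, sugars_g=9.0, sodium_mg=3)
        assert not classify_positive(fruit, ruleset).eligible

    def test_missing_limited_nutrient_disqualifies(self, ruleset):
        cheese = make_product(Category.dairy, subcategory="cheeses",
                              total_fat_g=4.0, sat_fat_g=2.0, sugars_g=1.0)  # sodium undeclared
        report = classify_positive(cheese, ruleset)
        assert not report.eligible
        assert FailureReason.missing_nutrient in report.failure_reasons


class TestMixtures:
    def test_grain_vegetable_mix_within_limits_is_eligible(self, ruleset):
        mix = make_product(Category.mixture, components={Category.grains, Category.vegetables},
                           additives={"salt", "spice"},
                           total_fat_g=3.0, sat_fat_g=0.5, sugars_g=2.0, sodium_mg=180)
        assert classify_positive(mix, ruleset).eligible

    def test_dairy_fruit_mix_is_not_combinable(self, ruleset):
        mix = make_product(Category.mixture, components={Category.dairy, Category.fruits},
                           total_fat_g=2.0, sat_fat_g=1.0, sugars_g=5.0, sodium_mg=50)
        report = classify_positive(mix, ruleset)
        assert not report.eligible
        assert FailureReason.combination_violation in report.failure_reasons

    def test_mixture_whitelist_violation(self, ruleset):
        mix = make_product(Category.mixture, components={Category.legumes, Category.seeds_nuts},
                           additives={"preservative"},
                           total_fat_g=10.0, sat_fat_g=1.5, sugars_g=2.0, sodium_mg=100)
        report = classify_positive(mix, ruleset)
        assert not report.eligible
        assert FailureReason.additive_violation in report.failure_reasons

    def test_most_restrictive_component_limit_wins(self, ruleset):
        rule = combined_mixture_rule({Category.grains, Category.vegetables}, ruleset)
        assert rule.max_limits["sodium_mg"].value == 200  # once for the whole product
        mix = make_product(Category.mixture, components={Category.grains, Category.vegetables},
                           total_fat_g=1.0, sat_fat_g=0.2, sugars_g=1.0, sodium_mg=250)
        assert not classify_positive(mix, ruleset).eligible

    def test_forbidden_flags_accumulate_across_components(self, ruleset):
        mix = make_product(Category.mixture, components={Category.grains, Category.fruits},
                           flags={ProcessingFlag.juiced},
                           total_fat_g=1.0, sat_fat_g=0.2, sugars_g=1.0, sodium_mg=50)
        assert not classify_positive(mix, ruleset).eligible


class TestWarningConsistency:
    def test_values_exactly_at_warning_thresholds_pass(self, ruleset):
        t = ruleset.warning_thresholds.solids
        fruit = make_product(Category.fruits, sugars_g=t["sugars_g"], sodium_mg=t["sodium_mg"],
                             sat_fat_g=t["sat_fat_g"], total_fat_g=t["sat_fat_g"] + 1)
        assert check_warning_consistency(fruit, ruleset).passed
        assert classify_positive(fruit, ruleset).eligible

    def test_exceeding_sugar_threshold_fails_even_with_no_category_limit(self, ruleset):
        t = ruleset.warning_thresholds.solids
        fruit = make_product(Category.fruits, sugars_g=t["sugars_g"] + 1, sodium_mg=5,
                             sat_fat_g=0.1, total_fat_g=0.5)
        report = classify_positive(fruit, ruleset)
        assert not report.eligible
        assert FailureReason.warning_conflict in report.failure_reasons

    def test_missing_sugar_value_cannot_be_certified(self, ruleset):
        fruit = make_product(Category.fruits, sodium_mg=5, sat_fat_g=0.1, total_fat_g=0.5)
        report = classify_positive(fruit, ruleset)
        assert not report.eligible
        assert FailureReason.missing_nutrient in report.failure_reasons


class TestEfsharibariBread:
    @pytest.mark.parametrize(
        "wg,na,kcal,expected",
        [
            (82.0, 380.0, 240.0, True),
            (80.0, 400.0, 250.0, True),   # all boundaries inclusive
            (79.9, 100.0, 200.0, False),
            (90.0, 400.1, 200.0, False),
            (90.0, 100.0, 250.1, False),
        ],
    )
    def test_three_printed_inequalities(self, wg, na, kcal, expected):
        bread = make_product(Category.bread, whole_grain_pct=wg, sodium_mg=na, energy_kcal=kcal)
        assert classify_efsharibari_bread(bread) is expected

    def test_missing_field_is_indeterminate_error(self):
        bread = make_product(Category.bread, whole_grain_pct=85.0, sodium_mg=300.0)
        with pytest.raises(ValueError, match="declared"):
            classify_efsharibari_bread(bread)

    def test_non_bread_rejected(self):
        with pytest.raises(ValueError, match="bread"):
            classify_efsharibari_bread(make_product(Category.grains))


class TestStructuralProperties:
    def test_positive_and_warning_labels_never_co_occur(self, ruleset):
        # scan the boundary grids: any eligible product must carry no warning
        for rule in ruleset.category_rules:
            for product in boundary_grid(rule):
                if classify_positive(product, ruleset).eligible:
                    assert evaluate_warnings(product, ruleset.warning_thresholds).exceeded == frozenset()

    def test_a_product_can_carry_neither_label(self, ruleset):
        plain = make_product(Category.other, sugars_g=2.0, sodium_mg=50, sat_fat_g=0.5, total_fat_g=1.0)
        decision = label_product(plain, ruleset)
        assert not decision.positive_eligible and not decision.warnings
        assert decision.label_class.value == "none"

    @settings(derandomize=True, max_examples=150)
    @given(
        sodium=st.floats(0, 600, allow_nan=False),
        bump=st.floats(0.001, 400, allow_nan=False),
        subcategory=st.sampled_from(["cheeses", "whole_grains", "legume_spreads", "vegetables"]),
    )
    def test_raising_sodium_never_flips_ineligible_to_eligible(self, ruleset, sodium, bump, subcategory):
        category = {"cheeses": Category.dairy, "whole_grains": Category.grains,
                    "legume_spreads": Category.legumes, "vegetables": Category.vegetables}[subcategory]
        base = make_product(category, subcategory=subcategory,
                            total_fat_g=2.0, sat_fat_g=1.0, sugars_g=1.0, sodium_mg=sodium)
        raised = make_product(category, subcategory=subcategory,
                              total_fat_g=2.0, sat_fat_g=1.0, sugars_g=1.0, sodium_mg=sodium + bump)
        if not classify_positive(base, ruleset).eligible:
            assert not classify_positive(raised, ruleset).eligible

    def test_failure_reasons_reconstruct_eligibility(self, ruleset):
        for rule in ruleset.category_rules:
            for product in boundary_grid(rule, eps=0.02):
                report = classify_positive(product, ruleset)
                assert report.eligible == (not report.failure_reasons)


def test_every_criteria_row_matches_brute_force_on_boundary_grid(ruleset):
    """Exhaustive grid per rule: limits at value and value +/- eps, each
    whitelist token (plus a non-whitelisted one) present/absent, each
    forbidden/required flag toggled — engine equals the independent oracle."""
    checked = 0
    for rule in ruleset.category_rules:
        for product in boundary_grid(rule):
            expected = brute_force_eligible(product, rule, ruleset.warning_thresholds)
            got = classify_positive(product, ruleset).eligible
            assert got == expected, (rule.subcategory_key, product)
            checked += 1
    assert checked > 1000


def test_individual_checks_report_offenders(ruleset):
    cheese_rule = rule_for(ruleset, "cheeses")
    bad = make_product(Category.dairy, subcategory="cheeses", additives={"salt", "sweetener"},
                       flags={ProcessingFlag.enriched}, total_fat_g=6.0, sat_fat_g=3.0,
                       sugars_g=1.0, sodium_mg=250)
    additives = check_additives(bad, cheese_rule)
    assert not additives.passed and additives.detail == ("sweetener",)
    limits = check_nutrient_limits(bad, cheese_rule)
    assert not limits.passed and len(limits.detail) == 2
    flags = check_processing_flags(bad, cheese_rule)
    assert not flags.passed
    combo = check_combination(
        make_product(Category.mixture, components={Category.dairy, Category.grains}), ruleset
    )
    assert not combo.passed and combo.detail == ("dairy",)
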