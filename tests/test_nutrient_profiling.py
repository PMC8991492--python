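import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from foodbench.nutrient_profiling import (
    MissingNutrientError,
    NOVARules,
    Product,
    ProfilingError,
    UnknownCategoryError,
    WHORuleTable,
    WHOThresholds,
    nova_group,
    nutriscore,
    profile_products,
    who_permitted,
)
from panel import PANEL


def make_product(**kwargs) -> Product:
    defaults = dict(
        product_id="p1", energy_kj=0, sugars_g=0, saturated_fat_g=0,
        sodium_mg=0, fibre_g=0, protein_g=0,
    )
    defaults.update(kwargs)
    return Product(**defaults)


# ---------------------------------------------------------------------------
# Nutri-Score
# ---------------------------------------------------------------------------


class TestNutriScorePanel:
    @pytest.mark.parametrize(
        "product,negative,final,klass,protein_counted",
        PANEL,
        ids=[p[0].product_id for p in PANEL],
    )
    def test_hand_scored(self, product, negative, final, klass, protein_counted):
        res = nutriscore(product)
        assert res.negative_points == negative
        assert res.final_score == final
        assert res.klass == klass
        assert res.protein_counted == protein_counted

    def test_negative_points_sum(self):
        for product, *_ in PANEL:
            res = nutriscore(product)
            assert res.negative_points == (
                res.energy_pts + res.sugars_pts + res.saturated_fat_pts + res.sodium_pts
            )
            assert 0 <= res.negative_points <= 40
            assert res.final_score == res.negative_points - res.positive_points


class TestNutriScoreRules:
    def test_water_is_class_a_regardless(self):
        res = nutriscore(
            make_product(is_beverage=True, is_water=True, sugars_g=13, energy_kj=260)
        )
        assert res.klass == "A"

    def test_full_fruit_veg_food(self):
        res = nutriscore(make_product(fruit_veg_pct=100))
        assert res.negative_points == 0
        assert res.fruit_veg_pts == 5
        assert res.final_score == -5
        assert res.klass == "A"

    def test_all_negative_components_saturate(self):
        res = nutriscore(
            make_product(energy_kj=4000, sugars_g=50, saturated_fat_g=20, sodium_mg=2000)
        )
        assert (res.energy_pts, res.sugars_pts, res.saturated_fat_pts, res.sodium_pts) == (
            10, 10, 10, 10,
        )
        assert res.final_score == 40 and res.klass == "E"

    def test_cheese_keeps_protein_at_high_n(self):
        cheese = make_product(
            is_cheese=True, energy_kj=1300, sugars_g=2, saturated_fat_g=8.5,
            sodium_mg=400, protein_g=25,
        )
        res = nutriscore(cheese)
        assert res.negative_points == 15
        assert res.protein_counted is True
        assert res.final_score == 10

    def test_negative_thresholds_strictly_greater(self):
        # a value exactly at a threshold earns no extra point
        at = nutriscore(make_product(sugars_g=4.5))
        above = nutriscore(make_product(sugars_g=4.5001))
        assert at.sugars_pts == 0 and above.sugars_pts == 1

    def test_added_fat_ratio_boundary_inclusive(self):
        below = make_product(is_added_fat=True, saturated_fat_g=4.99, total_fat_g=50)
        at = make_product(is_added_fat=True, saturated_fat_g=5, total_fat_g=50)
        assert nutriscore(below).saturated_fat_pts == 0
        assert nutriscore(at).saturated_fat_pts == 1

    def test_missing_nutrient_named(self):
        df = pd.DataFrame([{"product_id": "x", "who_category": "bread",
                            "energy_kj": 1, "sugars_g": 1, "saturated_fat_g": 1,
                            "fibre_g": 1, "protein_g": 1}])
        with pytest.raises(MissingNutrientError, match="sodium_mg"):
            profile_products(df)

    def test_negative_nutrient_rejected(self):
        with pytest.raises(ValidationError):
            make_product(sugars_g=-1)

    def test_inconsistent_flags_rejected(self):
        with pytest.raises(ValidationError):
            make_product(is_cheese=True, is_added_fat=True)
        with pytest.raises(ValidationError):
            make_product(is_water=True)  # water without is_beverage

    def test_added_fat_requires_total_fat(self):
        with pytest.raises(ValidationError, match="total_fat_g"):
            make_product(is_added_fat=True)


@st.composite
def food_nutrients(draw):
    return dict(
        energy_kj=draw(st.floats(0, 4000)),
        sugars_g=draw(st.floats(0, 100)),
        saturated_fat_g=draw(st.floats(0, 50)),
        sodium_mg=draw(st.floats(0, 3000)),
        fibre_g=draw(st.floats(0, 20)),
        protein_g=draw(st.floats(0, 40)),
        fruit_veg_pct=draw(st.floats(0, 100)),
        is_beverage=draw(st.booleans()),
    )


class TestNutriScoreMonotonicity:
    @settings(max_examples=150, deadline=None)
    @given(base=food_nutrients(), bump=st.floats(0.01, 30))
    def test_more_sugar_never_lowers_score(self, base, bump):
        lo = nutriscore(make_product(**base))
        base["sugars_g"] = min(base["sugars_g"] + bump, 1000)
        hi = nutriscore(make_product(**base))
        assert hi.final_score >= lo.final_score

    @settings(max_examples=150, deadline=None)
    @given(base=food_nutrients(), bump=st.floats(0.01, 10))
    def test_more_fibre_never_raises_score(self, base, bump):
        lo = nutriscore(make_product(**base))
        base["fibre_g"] = base["fibre_g"] + bump
        hi = nutriscore(make_product(**base))
        assert hi.final_score <= lo.final_score


# ---------------------------------------------------------------------------
# WHO model
# ---------------------------------------------------------------------------

TOY_RULES = WHORuleTable(
    version="toy",
    categories={
        "catX": WHOThresholds(max_total_sugars_g=10, max_salt_g=1),
        "banned": WHOThresholds(always_prohibited=True),
    },
)


class TestWHO:
    def test_prohibited_category_dominates(self):
        p = make_product(who_category="banned")
        decision = who_permitted(p, TOY_RULES)
        assert not decision.permitted
        assert decision.violations == ("category",)

    def test_all_thresholds_pass(self):
        p = make_product(who_category="catX", sugars_g=9, salt_g=0.5)
        assert who_permitted(p, TOY_RULES).permitted

    def test_boundary_is_inclusive(self):
        at = make_product(who_category="catX", sugars_g=10.0, salt_g=0.5)
        over = make_product(who_category="catX", sugars_g=10.0001, salt_g=0.5)
        assert who_permitted(at, TOY_RULES).permitted
        assert not who_permitted(over, TOY_RULES).permitted

    def test_violation_list_complete(self):
        p = make_product(who_category="catX", sugars_g=11, salt_g=2)
        decision = who_permitted(p, TOY_RULES)
        assert len(decision.violations) == 2  # not short-circuited

    def test_unknown_category_named(self):
        with pytest.raises(UnknownCategoryError, match="mystery"):
            who_permitted(make_product(who_category="mystery"), TOY_RULES)

    def test_missing_required_nutrient_errors_not_permits(self):
        rules = WHORuleTable(
            version="toy", categories={"c": WHOThresholds(max_added_sugars_g=5)}
        )
        with pytest.raises(MissingNutrientError, match="added_sugars_g"):
            who_permitted(make_product(who_category="c"), rules)

    def test_salt_derived_from_sodium(self):
        # 480 mg sodium -> 1.2 g salt > 1 g limit
        p = make_product(who_category="catX", sodium_mg=480)
        assert not who_permitted(p, TOY_RULES).permitted
        p2 = make_product(who_category="catX", sodium_mg=400)  # exactly 1.0 g
        assert who_permitted(p2, TOY_RULES).permitted

    def test_nss_marker_prohibited(self):
        rules = WHORuleTable(
            version="toy",
            categories={"c": WHOThresholds(prohibit_non_sugar_sweeteners=True)},
        )
        sweet = make_product(who_category="c", ingredient_markers=frozenset({"sweetener"}))
        plain = make_product(who_category="c")
        assert not who_permitted(sweet, rules).permitted
        assert who_permitted(plain, rules).permitted

    def test_empty_rule_category_rejected(self):
        with pytest.raises(ValidationError):
            WHOThresholds()


# ---------------------------------------------------------------------------
# NOVA
# ---------------------------------------------------------------------------


class TestNOVA:
    def test_marker_forces_group_4(self, nova_rules):
        p = make_product(
            who_category="bread", ingredient_markers=frozenset({"flavouring"})
        )
        assert nova_group(p, nova_rules) == 4

    def test_override_precedence(self, nova_rules):
        p = make_product(
            who_category="bread",
            ingredient_markers=frozenset({"flavouring"}),
            nova_group_override=1,
        )
        assert nova_group(p, nova_rules) == 1

    def test_category_default(self):
        rules = NOVARules(
            version="toy",
            group4_markers=frozenset({"flavouring"}),
            category_groups={"fresh_vegetables": 1},
            default_group=3,
        )
        p = make_product(who_category="fresh_vegetables")
        assert nova_group(p, rules) == 1

    def test_default_group_fallback(self, nova_rules):
        p = make_product(who_category="unmapped_cat")
        assert nova_group(p, nova_rules) == nova_rules.default_group

    def test_override_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            make_product(nova_group_override=5)
        df = pd.DataFrame([{"product_id": "x", "who_category": "chocolate_confectionery",
                            "energy_kj": 1, "sugars_g": 1, "saturated_fat_g": 1,
                            "sodium_mg": 1, "fibre_g": 1, "protein_g": 1,
                            "nova_group_override": 7}])
        with pytest.raises(ProfilingError, match="nova_group_override"):
            profile_products(df)


# ---------------------------------------------------------------------------
# Combined profiling
# ---------------------------------------------------------------------------


class TestProfileProducts:
    def test_partition_over_classifiers(self, demo_bundle, who_rules, nova_rules):
        out = profile_products(demo_bundle.products, who_rules, nova_rules)
        assert len(out) == len(demo_bundle.products)
        assert set(out["nutri_class"]) <= set("ABCDE")
        assert out["nova_group"].isin([1, 2, 3, 4]).all()
        assert out["permitted"].isin([True, False]).all()

    def test_fruit_veg_missing_imputed_as_zero(self):
        df = pd.DataFrame([{"product_id": "x", "who_category": "bread",
                            "energy_kj": 0, "sugars_g": 0, "saturated_fat_g": 0,
                            "sodium_mg": 0, "fibre_g": 0, "protein_g": 0,
                            "total_fat_g": 1.0}])
        out = profile_products(df)
        assert out.loc[0, "fruit_veg_pts"] == 0
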