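import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import rank_sum_exact_p, signed_rank_exact_p
from foodbench.commitment_scoring import (
    DOMAINS,
    CommitmentSheet,
    IndicatorScore,
    ScoringError,
    UndefinedDomainError,
    WeightTable,
    domain_score,
    engagement_effect,
    overall_score,
    participation_gap,
    rank_sum_test,
    score_frame,
    signed_rank_test,
)


def make_sheet(scores_by_domain, industry="manufacturer", inapplicable=()):
    """scores_by_domain: domain -> list of (raw, max)."""
    indicators = []
    for domain in DOMAINS:
        for i, (raw, mx) in enumerate(scores_by_domain.get(domain, [(0, 5)])):
            indicators.append(
                IndicatorScore(
                    indicator_id=f"{domain}_{i}",
                    domain=domain,
                    raw=raw,
                    max=mx,
                    applicable=(domain, i) not in inapplicable,
                )
            )
    return CommitmentSheet("C1", industry, "verified", tuple(indicators))


class TestDomainScore:
    def test_full_marks(self):
        sheet = make_sheet({"promotion": [(5, 5), (10, 10)]})
        assert domain_score(sheet, "promotion") == 100.0

    def test_zero_marks(self):
        sheet = make_sheet({"promotion": [(0, 5), (0, 10)]})
        assert domain_score(sheet, "promotion") == 0.0

    def test_hand_arithmetic(self):
        sheet = make_sheet({"product_formulation": [(3, 5), (1, 5)]})
        assert domain_score(sheet, "product_formulation") == pytest.approx(40.0)

    def test_inapplicable_excluded_from_both_sums(self):
        sheet = make_sheet(
            {"promotion": [(3, 5), (0, 5)]}, inapplicable={("promotion", 1)}
        )
        assert domain_score(sheet, "promotion") == pytest.approx(60.0)

    def test_all_inapplicable_is_undefined_not_zero(self):
        sheet = make_sheet(
            {"promotion": [(0, 5)]}, inapplicable={("promotion", 0)}
        )
        with pytest.raises(UndefinedDomainError):
            domain_score(sheet, "promotion")

    def test_raw_above_max_rejected(self):
        with pytest.raises(ScoringError):
            IndicatorScore("i", "promotion", raw=6, max=5)

    def test_missing_domain_rejected(self):
        with pytest.raises(ScoringError, match="accessibility"):
            CommitmentSheet(
                "C1", "manufacturer", "verified",
                tuple(
                    IndicatorScore(f"{d}_0", d, 1, 5)
                    for d in DOMAINS if d != "accessibility"
                ),
            )

    @settings(max_examples=50, deadline=None)
    @given(scale=st.floats(0.1, 50), raws=st.lists(st.floats(0, 5), min_size=1, max_size=6))
    def test_scale_invariance(self, scale, raws):
        base = make_sheet({"promotion": [(r, 5) for r in raws]})
        scaled = make_sheet({"promotion": [(r * scale, 5 * scale) for r in raws]})
        assert domain_score(base, "promotion") == pytest.approx(
            domain_score(scaled, "promotion")
        )


class TestOverallScore:
    def test_uniform_weights_constant_domains(self):
        sheet = make_sheet({d: [(3, 5)] for d in DOMAINS})
        assert overall_score(sheet, WeightTable.uniform()) == pytest.approx(60.0)

    def test_hand_weighted(self):
        weights = WeightTable(
            {
                "manufacturer": {
                    "product_formulation": 0.5,
                    **{d: 0.1 for d in DOMAINS if d != "product_formulation"},
                }
            }
        )
        sheet = make_sheet(
            {
                "product_formulation": [(5, 5)],
                **{d: [(0, 5)] for d in DOMAINS if d != "product_formulation"},
            }
        )
        assert overall_score(sheet, weights) == pytest.approx(50.0)

    def test_convex_combination_bounds(self):
        sheet = make_sheet({d: [(i, 5)] for i, d in enumerate(DOMAINS)})
        weights = WeightTable.uniform()
        overall = overall_score(sheet, weights)
        scores = [domain_score(sheet, d) for d in DOMAINS]
        assert min(scores) <= overall <= max(scores)

    def test_monotone_in_any_raw(self):
        lo = make_sheet({d: [(2, 5)] for d in DOMAINS})
        hi = make_sheet({**{d: [(2, 5)] for d in DOMAINS}, "promotion": [(4, 5)]})
        w = WeightTable.uniform()
        assert overall_score(hi, w) >= overall_score(lo, w)

    def test_renormalises_on_undefined_domain(self):
        sheet = make_sheet(
            {d: [(4, 5)] for d in DOMAINS}, inapplicable={("accessibility", 0)}
        )
        assert overall_score(sheet, WeightTable.uniform()) == pytest.approx(80.0)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ScoringError, match="sum to 1"):
            WeightTable({"manufacturer": {d: 0.2 for d in DOMAINS}})


class TestSignedRank:
    def test_constant_uplift_n18_exact_tail(self):
        pre = np.arange(18, dtype=float)
        post = pre + 5.0
        res = engagement_effect(pre, post)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1.0 / 2**18)
        assert res.extra["median_post"] - res.extra["median_pre"] == pytest.approx(5.0)

    def test_no_nonzero_pairs_refused(self):
        with pytest.raises(ScoringError, match="non-zero"):
            engagement_effect([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=7)
        p_fwd = signed_rank_test(d, alternative="greater").p_value
        p_rev = signed_rank_test(-d, alternative="greater").p_value
        # reflection symmetry: P(W>=w) + P(W>=S-w) = 1 + P(W=w), so the
        # flipped p equals 1 - p up to the point mass at the observed W
        point_mass = (
            signed_rank_exact_p(d, "greater") + signed_rank_exact_p(d, "less") - 1.0
        )
        assert point_mass >= -1e-12
        assert p_fwd + p_rev == pytest.approx(1.0 + point_mass, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            d = rng.normal(size=n)
            for alt in ("greater", "less", "two-sided"):
                mine = signed_rank_test(d, alternative=alt).p_value
                assert mine == pytest.approx(signed_rank_exact_p(d, alt), abs=1e-12)

    def test_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            d = rng.integers(-3, 4, size=7).astype(float)
            if (d != 0).sum() < 2:
                continue
            mine = signed_rank_test(d, alternative="greater").p_value
            assert mine == pytest.approx(signed_rank_exact_p(d, "greater"), abs=1e-12)

    def test_pratt_zero_method_supported(self):
        d = np.array([0.0, 1.0, 2.0, -1.5, 3.0])
        res = signed_rank_test(d, zero_method="pratt")
        assert res.extra["n_zero_dropped"] == 1

    def test_large_n_uses_approximation(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.5, 1.0, size=40)
        res = signed_rank_test(d)
        assert res.method == "normal_approx"
        assert 0.0 <= res.p_value <= 1.0


class TestRankSum:
    def test_extreme_split_exact_p(self):
        res = participation_gap([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        res = participation_gap([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        a, b = [1.0, 5.0, 2.5], [2.0, 7.0, 0.5, 4.0]
        assert participation_gap(a, b).p_value == pytest.approx(
            participation_gap(b, a).p_value
        )

    def test_empty_group_refused(self):
        with pytest.raises(ScoringError, match="empty"):
            participation_gap([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 4), (3, 5), (4, 3)])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(15):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            mine = rank_sum_test(x, y).p_value
            assert mine == pytest.approx(rank_sum_exact_p(x, y), abs=1e-12)

    def test_matches_enumeration_with_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.integers(0, 4, size=4).astype(float)
            y = rng.integers(0, 4, size=4).astype(float)
            mine = rank_sum_test(x, y).p_value
            assert mine == pytest.approx(rank_sum_exact_p(x, y), abs=1e-12)

    def test_large_n_uses_approximation(self):
        rng = np.random.default_rng(6)
        res = rank_sum_test(rng.normal(size=15), rng.normal(1, 1, size=15))
        assert res.method == "normal_approx"


class TestScoreFrame:
    def test_synthetic_round_trip(self, demo_bundle, uniform_weights):
        scores = score_frame(demo_bundle.commitments, uniform_weights)
        assert set(scores["stage"]) == {"public_only", "verified"}
        assert scores["overall"].between(0, 100).all()
        for d in DOMAINS:
            assert scores[d].dropna().between(0, 100).all()
        # verified >= public for every company (uplift never lowers)
        wide = scores.pivot(index="company_id", columns="stage", values="overall")
        assert (wide["verified"] >= wide["public_only"] - 1e-9).all()
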