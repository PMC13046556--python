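"""Unit and property tests for the rank-based statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfosnet.rank_stats import (
    adjust_bh_fdr,
    dunn_posthoc,
    effect_size,
    kruskal_wallis_test,
    ks_two_sample_test,
    mann_whitney_test,
    wilcoxon_signed_rank_test,
)

from _oracles import dunn_z_oracle, mwu_enum_p, signed_rank_enum_p

floats = st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False)


class TestMannWhitney:
    def test_full_separation_6v9_gives_statistic_54(self):
        x = np.arange(100, 109)  # all nine values above the six below
        y = np.arange(1, 7)
        res = mann_whitney_test(x, y)
        assert res.statistic == 54
        assert res.n_per_group == [9, 6]

    def test_asymptotic_mode_reproduces_reported_behavioral_p(self):
        # continuity-corrected normal approximation at full 9-vs-6 separation
        res = mann_whitney_test(np.arange(100, 109), np.arange(1, 7), mode="asymptotic")
        assert res.mode == "asymptotic"
        assert res.p_value == pytest.approx(0.0018, abs=2e-4)

    def test_identical_samples_sit_at_null_center(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney_test(x, x)
        assert res.statistic == len(x) ** 2 / 2
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_tiny_example_exact_p_from_enumeration(self):
        res = mann_whitney_test([1, 3], [2, 4])
        assert res.statistic == 1
        assert res.mode == "exact"
        assert res.p_value == pytest.approx(4 / 6)

    def test_swap_symmetry_maps_u_to_complement(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=7)
        a = mann_whitney_test(x, y)
        b = mann_whitney_test(y, x)
        assert a.statistic + b.statistic == 35
        assert a.p_value == pytest.approx(b.p_value)

    def test_exact_p_equals_full_enumeration_small_samples(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(2, 5, size=2)
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            for side in ("two-sided", "greater", "less"):
                res = mann_whitney_test(x, y, sidedness=side)
                assert res.mode == "exact"
                assert res.p_value == pytest.approx(mwu_enum_p(x, y, side))

    def test_ties_fall_back_to_corrected_normal(self):
        res = mann_whitney_test([1, 2, 2, 3], [2, 3, 4, 4])
        assert res.mode == "asymptotic"
        assert 0 < res.p_value <= 1

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_test([], [1.0])


class TestSignedRank:
    def test_all_positive_differences_hit_maximum(self):
        res = wilcoxon_signed_rank_test([0] * 5, [1, 2, 3, 4, 5])
        assert res.statistic == 15  # 5*6/2

    def test_tied_magnitudes_average_ranks(self):
        res = wilcoxon_signed_rank_test([0, 0], [1, -1])
        assert res.statistic == 1.5
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            wilcoxon_signed_rank_test([1.0, 2.0], [1.0, 2.0])

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank_test([1, 1, 1, 1], [1, 2, 3, 0.5])
        assert res.n_per_group == [3]

    def test_exact_p_matches_sign_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 8))
            before, after = rng.normal(size=n), rng.normal(size=n)
            res = wilcoxon_signed_rank_test(before, after)
            assert res.mode == "exact"
            assert res.p_value == pytest.approx(signed_rank_enum_p(before, after))


class TestKruskalWallis:
    def test_three_groups_have_two_degrees_of_freedom(self, rng):
        res = kruskal_wallis_test([rng.normal(size=6), rng.normal(size=6), rng.normal(size=9)])
        assert res.df == 2

    def test_hand_computed_h(self):
        res = kruskal_wallis_test([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32 / 7)

    def test_all_tied_input_is_degenerate_not_an_error(self):
        res = kruskal_wallis_test([[2.0, 2.0], [2.0, 2.0]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis_test([[1.0, 2.0]])


class TestDunn:
    def test_identical_groups_give_zero_z(self):
        vals = [1.0, 2.0, 3.0]
        res = dunn_posthoc([vals, vals, [10.0, 11.0, 12.0]], adjust="none")
        first = next(r for r in res if r.pair == ("group0", "group1"))
        assert first.statistic == pytest.approx(0.0)
        assert first.p_value == pytest.approx(1.0)

    def test_three_groups_give_three_pairs(self, rng):
        res = dunn_posthoc([rng.normal(size=6), rng.normal(size=6), rng.normal(size=9)])
        assert len(res) == 3
        assert all(r.p_adjusted is not None for r in res)

    def test_z_matches_textbook_formula(self, rng):
        groups = [rng.integers(0, 8, size=n).astype(float) for n in (5, 7, 6)]
        res = dunn_posthoc(groups, adjust="none")
        np.testing.assert_allclose([r.statistic for r in res], dunn_z_oracle(groups))

    def test_bh_adjustment_is_monotone_in_raw_p(self, rng):
        res = dunn_posthoc([rng.normal(size=5) + s for s in (0, 1, 3)], adjust="bh")
        by_raw = sorted(res, key=lambda r: r.p_value)
        adj = [r.p_adjusted for r in by_raw]
        assert adj == sorted(adj)


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        res = ks_two_sample_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_disjoint_supports(self):
        res = ks_two_sample_test([1, 2, 3], [10, 11, 12])
        assert res.statistic == 1.0

    def test_interleaved_example(self):
        res = ks_two_sample_test([1, 3, 5], [2, 4, 6])
        assert res.statistic == pytest.approx(1 / 3)
        assert res.mode == "exact"

    def test_statistic_on_sixths_grid_for_n6(self, rng):
        # with n1 = n2 = 6, D must be a multiple of 1/6
        x, y = rng.normal(size=6), rng.normal(size=6)
        res = ks_two_sample_test(x, y)
        assert (6 * res.statistic) == pytest.approx(round(6 * res.statistic))


class TestBenjaminiHochberg:
    def test_hand_worked_example(self):
        assert adjust_bh_fdr([0.005, 0.01, 0.03, 0.04]) == pytest.approx(
            [0.02, 0.02, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert adjust_bh_fdr([0.3]) == [pytest.approx(0.3)]

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            adjust_bh_fdr([0.5, 1.2])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_never_decreases_any_p(self, ps):
        adj = adjust_bh_fdr(ps)
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        assert all(a <= 1 for a in adj)
        # step-up monotone: adjusted order agrees with raw order
        order = np.argsort(ps)
        assert all(
            adj[order[i]] <= adj[order[i + 1]] + 1e-12 for i in range(len(ps) - 1)
        )


class TestEffectSize:
    def test_equal_means_give_zero(self):
        assert effect_size([1, 2, 3], [3, 2, 1]).value == pytest.approx(0.0)

    def test_hand_pooled_sd_example(self):
        assert effect_size([1, 2, 3], [2, 3, 4], kind="cohens_d").value == pytest.approx(-1.0)

    def test_auto_selects_by_balance(self, rng):
        assert effect_size(rng.normal(size=6), rng.normal(size=9)).kind == "hedges_g"
        assert effect_size(rng.normal(size=6), rng.normal(size=6)).kind == "cohens_d"

    def test_hedges_shrinks_cohen(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=9)
        d = effect_size(x, y, kind="cohens_d")
        g = effect_size(x, y, kind="hedges_g")
        assert g.value == pytest.approx(d.value * (1 - 3 / (4 * 15 - 9)))
        assert abs(g.value) <= abs(d.value)

    def test_sign_antisymmetry(self, rng):
        x, y = rng.normal(size=5), rng.normal(size=5)
        assert effect_size(x, y).value == pytest.approx(-effect_size(y, x).value)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            effect_size([2.0, 2.0], [2.0, 2.0])


@settings(deadline=None, max_examples=40)
@given(
    st.lists(floats, min_size=2, max_size=6),
    st.lists(floats, min_size=2, max_size=6),
)
def test_null_center_rejection_consistency(x, y):
    """p-values are always valid probabilities across arbitrary inputs."""
    for res in (mann_whitney_test(x, y), ks_two_sample_test(x, y)):
        assert 0 <= res.p_value <= 1
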