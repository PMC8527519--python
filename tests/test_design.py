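"""Funnel combinatorics: canonical forms, counting, balance."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from magicpop.design import (
    BalanceSearchError,
    DesignError,
    Funnel,
    InfeasibleDesignError,
    InvalidFunnelError,
    balance_profile,
    basic_design,
    canonical_funnel,
    count_balanced_set_orbits_8,
    count_full_funnels,
    custom_design,
    enumerate_balanced_sets_8,
    enumerate_full_funnels,
    find_balanced_sets,
    full_design,
    is_balanced,
    minimal_balanced_set_size,
    sample_unbalanced,
)


def brute_force_classes(n):
    """Oracle: canonicalize every permutation of 1..n and count classes."""
    return {canonical_funnel(p) for p in itertools.permutations(range(1, n + 1))}


class TestCounting:
    @pytest.mark.parametrize("n,expected", [(2, 1), (4, 3), (8, 315)])
    def test_closed_form_power_of_two(self, n, expected):
        assert count_full_funnels(n) == expected

    def test_sixteen_founders_closed_form(self):
        import math
        assert count_full_funnels(16) == math.factorial(16) // 2 ** 15

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
    def test_count_matches_brute_force_enumeration(self, n):
        assert count_full_funnels(n) == len(brute_force_classes(n))

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 8])
    def test_enumeration_is_exhaustive_and_duplicate_free(self, n):
        funnels = enumerate_full_funnels(n)
        assert len(funnels) == len(set(funnels)) == count_full_funnels(n)
        assert set(funnels) == brute_force_classes(n)

    def test_enumerate_four_founders(self):
        assert {f.text() for f in enumerate_full_funnels(4)} == {"1234", "1324", "1423"}

    def test_large_space_requires_lazy(self):
        with pytest.raises(DesignError, match="lazy"):
            enumerate_full_funnels(16)
        first = next(iter(enumerate_full_funnels(16, lazy=True)))
        assert first.n == 16

    def test_invalid_founder_count(self):
        with pytest.raises(DesignError):
            count_full_funnels(1)


class TestCanonical:
    def test_equivalent_four_founder_orderings(self):
        # all direction swaps of ((1x2)x(3x4)) name the same crossing scheme
        for perm in ("1234", "1243", "2134", "2143", "3412", "3421", "4312", "4321"):
            assert canonical_funnel(perm).text() == "1234"

    def test_already_canonical_is_fixed_point(self):
        assert canonical_funnel("1234").text() == "1234"

    @settings(max_examples=50, derandomize=True)
    @given(st.permutations(list(range(1, 9))), st.randoms(use_true_random=False))
    def test_subtree_swaps_preserve_canonical_form(self, perm, rnd):
        """Swapping the two halves of any block leaves the funnel unchanged."""
        base = canonical_funnel(perm)
        order = list(perm)
        for _ in range(4):
            size = rnd.choice([2, 4, 8])
            start = rnd.choice(range(0, 8, size))
            block = order[start:start + size]
            order[start:start + size] = block[size // 2:] + block[:size // 2]
        assert canonical_funnel(order) == base

    def test_rejects_non_permutation(self):
        with pytest.raises(InvalidFunnelError):
            canonical_funnel([1, 1, 2, 3])

    def test_text_roundtrip(self):
        for text in ("1234", "12345678", "((1x2)x(3x4))", "1-2-3-4", "1 2 3 4"):
            f = Funnel.from_text(text)
            assert Funnel.from_text(f.text()) == f
            assert Funnel.from_text(f.text(nested=True)) == f


class TestBalance:
    def test_balanced_four_founder_set_profile(self):
        profile = balance_profile([canonical_funnel(t) for t in ("1234", "1324", "1423")])
        assert set(profile[1].values()) == {1} and len(profile[1]) == 6
        assert set(profile[2].values()) == {2} and len(profile[2]) == 6

    def test_single_funnel_profile(self):
        profile = balance_profile([canonical_funnel("1234")])
        assert profile[1][(1, 2)] == 1
        assert (1, 3) not in profile[1]
        assert profile[2][(1, 3)] == 1

    def test_balanced_examples(self):
        assert is_balanced([canonical_funnel(t) for t in ("1234", "1324", "1423")])
        assert not is_balanced([canonical_funnel("1234")])
        assert not is_balanced([basic_design(8).funnels[0]])

    def test_full_eight_founder_design_is_balanced(self):
        funnels = enumerate_full_funnels(8)
        assert is_balanced(funnels)
        profile = balance_profile(funnels)
        # 28 pairs exhaust 315 funnels x (4, 8, 16) pair slots per generation
        assert set(profile[1].values()) == {315 * 4 // 28}
        assert set(profile[2].values()) == {315 * 8 // 28}
        assert set(profile[3].values()) == {315 * 16 // 28}

    def test_mixed_founder_counts_rejected(self):
        with pytest.raises(DesignError):
            balance_profile([canonical_funnel("1234"), canonical_funnel("123456")])


class TestBalancedSets8:
    def test_every_set_is_balanced_with_124_profile(self):
        sets = enumerate_balanced_sets_8()
        for s in sets:
            profile = balance_profile(list(s))
            assert len(profile[1]) == 28 and set(profile[1].values()) == {1}
            assert set(profile[2].values()) == {2}
            assert set(profile[3].values()) == {4}

    def test_two_way_levels_partition_all_pairs(self):
        # 7 funnels x 4 two-way pairs = 28 = C(8,2), each exactly once
        for s in enumerate_balanced_sets_8()[:50]:
            pairs = [p for f in s for p in f.pairs_by_generation()[1]]
            assert len(pairs) == 28 and len(set(pairs)) == 28

    def test_all_sets_are_founder_relabelings_of_one_scheme(self):
        assert count_balanced_set_orbits_8() == 1


class TestFindBalanced:
    def test_four_founders_unique_minimal_set(self):
        funnels = find_balanced_sets(4, 1, seed=0)
        assert {f.text() for f in funnels} == {"1234", "1324", "1423"}

    def test_eight_founders_single_set(self):
        funnels = find_balanced_sets(8, 1, seed=3)
        assert len(funnels) == 7 and is_balanced(funnels)

    def test_eight_founders_two_nonoverlapping_sets(self):
        funnels = find_balanced_sets(8, 2, seed=3)
        assert len(funnels) == len(set(funnels)) == 14
        assert set(balance_profile(funnels)[1].values()) == {2}

    def test_second_set_infeasible_for_four_founders(self):
        with pytest.raises(InfeasibleDesignError):
            find_balanced_sets(4, 2, seed=0)

    @pytest.mark.parametrize("n,size", [(4, 3), (8, 7), (16, 15), (5, 5), (6, 15)])
    def test_minimal_set_size_divisibility(self, n, size):
        # the pair slots per generation must split evenly over all C(n,2) pairs
        assert minimal_balanced_set_size(n) == size

    def test_annealing_search_non_power_of_two(self):
        funnels = find_balanced_sets(5, 1, seed=12)
        assert len(funnels) == 5 and is_balanced(funnels)

    def test_search_failure_is_an_error_never_an_unbalanced_result(self):
        from magicpop.design import _anneal_balanced
        rng = np.random.default_rng(0)
        with pytest.raises(BalanceSearchError, match="imbalance"):
            _anneal_balanced(16, 15, rng, max_iters=30, restarts=1)


class TestSampling:
    def test_exhaustive_sample_is_full_design(self):
        assert set(sample_unbalanced(8, 315, seed=1)) == set(enumerate_full_funnels(8))

    def test_single_funnel_is_basic(self):
        (f,) = sample_unbalanced(8, 1, seed=1)
        assert f.n == 8

    def test_seed_reproducibility_and_seed_sensitivity(self):
        a = sample_unbalanced(8, 7, seed=11)
        b = sample_unbalanced(8, 7, seed=11)
        c = sample_unbalanced(8, 7, seed=12)
        assert a == b
        assert set(a) != set(c)  # collision probability ~ 1/C(315,7)

    def test_distinctness_enforced(self):
        assert len(set(sample_unbalanced(4, 3, seed=0))) == 3
        with pytest.raises(DesignError):
            sample_unbalanced(4, 4, seed=0)


class TestDesignSpec:
    def test_basic_design_funnel_order(self):
        assert basic_design(8).funnels[0].order == tuple(range(1, 9))
        assert basic_design(4).funnels[0].text() == "1234"

    def test_schedule_length_mismatch(self):
        with pytest.raises(DesignError, match="length"):
            full_design(4, replicates=(1, 1, 1), selfing=(0, 4))

    def test_founder_range(self):
        with pytest.raises(DesignError):
            basic_design(129)
        with pytest.raises(DesignError):
            basic_design(2)

    def test_additional_cross_needs_ril_target(self):
        with pytest.raises(DesignError, match="n_rils_target"):
            basic_design(8, replicates=(1, 1, 1, 1), selfing=(0, 0, 0, 4),
                         additional_cross=True)

    def test_custom_design_from_text(self):
        d = custom_design(["1234", "1324"], replicates=(1, 2), selfing=(0, 4))
        assert d.n_founders == 4 and len(d.funnels) == 2

    def test_non_power_of_two_basic_design(self):
        d = basic_design(6)
        assert d.funnels[0].n_generations == 3
        assert len(d.replicates) == 3
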