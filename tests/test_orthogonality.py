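"""Orthogonality statistic and best-subset search tests.

Brute-force pair enumeration serves as the oracle for the optimized
max-min search throughout.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from switchscreen.errors import DegenerateProfileError, InvalidParameterError
from switchscreen.orthogonality import (
    FoldChangeMatrix,
    best_combination_bruteforce,
    best_combination_maxmin,
    centered_profile,
    classify_orthogonal,
    combination_distance,
    pair_cosine_distance,
    pairwise_distance_matrix,
    sweep_best_combinations,
)


def _matrix(arr):
    arr = np.asarray(arr, dtype=float)
    ids = [f"T{i+1}" for i in range(arr.shape[0])]
    cols = [f"S{j+1}" for j in range(arr.shape[1])]
    return FoldChangeMatrix.from_frame(pd.DataFrame(arr, index=ids, columns=cols))


def _random_fc(rng, n, m=None):
    return _matrix(rng.lognormal(0.0, 0.6, size=(n, m or n)))


def _identity_structured(n, on=5.0):
    arr = np.ones((n, n))
    np.fill_diagonal(arr, on)
    return _matrix(arr)


class TestPairDistance:
    def test_centered_profile(self):
        assert np.array_equal(centered_profile([1.0, 1.0]), [0.0, 0.0])
        assert np.array_equal(centered_profile([5.0, 1.0, 1.0]), [4.0, 0.0, 0.0])

    def test_identical_profiles_have_zero_distance(self):
        assert pair_cosine_distance([5, 1, 2], [5, 1, 2]) == pytest.approx(0.0)

    def test_disjoint_support_is_ideally_orthogonal(self):
        assert pair_cosine_distance([5, 1], [1, 5]) == pytest.approx(1.0)

    def test_worked_arithmetic_example(self):
        # centered (2,1) vs (1,2): 1 - 4/5
        assert pair_cosine_distance([3, 2], [2, 3]) == pytest.approx(0.2)

    def test_degenerate_all_one_profile_raises(self):
        with pytest.raises(DegenerateProfileError):
            pair_cosine_distance([1.0, 1.0], [5.0, 1.0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=30)
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        u = rng.lognormal(0.0, 0.8, 5)
        v = rng.lognormal(0.0, 0.8, 5)
        d = pair_cosine_distance(u, v)
        assert d == pytest.approx(pair_cosine_distance(v, u))
        assert 0.0 <= d <= 2.0


class TestCombinationDistance:
    def test_pair_combination_equals_single_distance(self):
        m = _matrix([[0.1, 1.0], [1.0, 0.1]])
        score = combination_distance(m, ["T1", "T2"])
        assert score.distance == pytest.approx(
            pair_cosine_distance([0.1, 1.0], [1.0, 0.1])
        )

    def test_minimum_over_pairs(self, rng):
        m = _random_fc(rng, 6)
        score = combination_distance(m, range(6), profile_mode="full")
        arr = m.values.to_numpy()
        oracle = min(
            pair_cosine_distance(arr[i], arr[j])
            for i, j in itertools.combinations(range(6), 2)
        )
        assert score.distance == pytest.approx(oracle)
        assert set(score.argmin_pair) <= set(score.combination)

    def test_subset_monotone_under_fixed_restriction(self, rng):
        m = _random_fc(rng, 7)
        sub = combination_distance(m, [0, 2, 4], profile_mode="full")
        sup = combination_distance(m, [0, 1, 2, 4, 6], profile_mode="full")
        assert sup.distance <= sub.distance + 1e-12

    def test_too_small_combination_raises(self):
        with pytest.raises(InvalidParameterError):
            combination_distance(_identity_structured(3), [0])


class TestBruteForce:
    def test_full_set_is_the_single_candidate(self, rng):
        m = _random_fc(rng, 5)
        best = best_combination_bruteforce(m, 5, profile_mode="full")
        assert best.combination == m.protein_ids

    def test_identity_structured_matrix_scores_one(self):
        best = best_combination_bruteforce(_identity_structured(6), 4)
        assert best.distance == pytest.approx(1.0)

    def test_planted_crosstalky_pair_is_excluded(self):
        # T1 also hits S2: pair (T1, T2) crosstalks, the best triple avoids it
        arr = np.ones((4, 4))
        np.fill_diagonal(arr, 0.1)
        arr[0, 1] = 0.4
        best = best_combination_bruteforce(_matrix(arr), 3, profile_mode="full")
        assert not {"T1", "T2"} <= set(best.combination)

    def test_n_out_of_range_raises(self):
        with pytest.raises(InvalidParameterError):
            best_combination_bruteforce(_identity_structured(4), 5)
        with pytest.raises(InvalidParameterError):
            best_combination_bruteforce(_identity_structured(4), 1)


class TestMaxMinSearch:
    def test_n_two_returns_global_max_pair(self, rng):
        m = _random_fc(rng, 8)
        best = best_combination_maxmin(m, 2, profile_mode="full")
        dist = pairwise_distance_matrix(m).to_numpy()
        iu = np.triu_indices(8, 1)
        assert best.distance == pytest.approx(dist[iu].max())

    @given(st.integers(0, 10_000))
    @settings(max_examples=25)
    def test_equals_bruteforce_with_identical_tie_breaking(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        m = _random_fc(rng, n)
        for size in range(2, n + 1):
            bf = best_combination_bruteforce(m, size, profile_mode="full")
            mm = best_combination_maxmin(m, size, profile_mode="full")
            assert mm.distance == pytest.approx(bf.distance, abs=1e-12)
            assert mm.combination == bf.combination

    def test_restricted_mode_delegates_to_exhaustive(self, rng):
        m = _random_fc(rng, 6)
        bf = best_combination_bruteforce(m, 3, profile_mode="restricted")
        mm = best_combination_maxmin(m, 3, profile_mode="restricted")
        assert mm.combination == bf.combination
        assert mm.distance == pytest.approx(bf.distance)


class TestSweep:
    def test_identity_structured_panel_sweeps_at_one(self):
        sweep = sweep_best_combinations(_identity_structured(17), 3, 17)
        assert all(s.distance == pytest.approx(1.0) for s in sweep)

    def test_monotone_non_increasing_and_matches_bruteforce(self, rng):
        m = _random_fc(rng, 8)
        sweep = sweep_best_combinations(m, 3, 8, profile_mode="full")
        dists = [s.distance for s in sweep]
        assert all(a >= b - 1e-12 for a, b in zip(dists, dists[1:]))
        for s in sweep:
            bf = best_combination_bruteforce(m, s.size, profile_mode="full")
            assert s.distance == pytest.approx(bf.distance)

    def test_single_crosstalk_pair_only_hurts_the_full_set(self):
        arr = np.ones((17, 17))
        np.fill_diagonal(arr, 0.1)
        arr[0, 1] = 0.4  # T1 crosstalks onto S2
        sweep = sweep_best_combinations(_matrix(arr), 3, 17, profile_mode="full")
        dists = {s.size: s.distance for s in sweep}
        assert all(dists[n] == pytest.approx(1.0) for n in range(3, 17))
        assert dists[17] < 0.9

    def test_range_validation(self):
        with pytest.raises(InvalidParameterError):
            sweep_best_combinations(_identity_structured(5), 3, 9)


class TestClassification:
    def test_threshold_boundary_is_inclusive(self):
        assert classify_orthogonal(0.7)
        assert not classify_orthogonal(0.69)

    def test_planted_panel_reproduces_labels(self, rng):
        arr = np.ones((5, 5))
        np.fill_diagonal(arr, 0.1)
        arr[0, 1] = 0.5  # planted crosstalk T1 -> S2
        m = _matrix(arr)
        bad = combination_distance(m, ["T1", "T2"], profile_mode="full")
        good = combination_distance(m, ["T2", "T3"], profile_mode="full")
        assert not classify_orthogonal(bad)
        assert classify_orthogonal(good)
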