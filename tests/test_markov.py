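"""Transition matrices, density, stationary distributions, GTE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aoiscan import (
    DegenerateInputError,
    InputError,
    TransitionMatrix,
    gaze_transition_entropy,
    matrix_density,
    scanning_statistics,
    stationary_distribution,
    transition_matrix,
)

from conftest import make_sequence


def tm_from_labels(labels, m):
    return transition_matrix(list(zip(labels[:-1], labels[1:])), m)


class TestTransitionMatrix:
    def test_tally(self):
        tm = transition_matrix([(1, 4), (4, 5), (5, 6)], m=10)
        assert tm.n_transitions == 3
        assert tm.counts[0, 3] == tm.counts[3, 4] == tm.counts[4, 5] == 1

    def test_row_normalization(self):
        tm = transition_matrix([(1, 2), (1, 2), (1, 3)], m=4)
        assert tm.probabilities[0].tolist() == pytest.approx([0, 2 / 3, 1 / 3, 0])
        # unvisited source rows stay all-zero
        assert np.all(tm.probabilities[3] == 0)

    def test_empty_is_all_zero(self):
        tm = transition_matrix([], m=5)
        assert tm.n_transitions == 0
        assert np.all(tm.probabilities == 0)

    @pytest.mark.parametrize("pair", [(0, 1), (1, 11), (3, 3)])
    def test_bad_ids_rejected(self, pair):
        with pytest.raises(InputError):
            transition_matrix([pair], m=10)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.integers(1, 6), min_size=2, max_size=200))
    def test_count_conservation(self, raw):
        # collapse repeats to obtain a valid cleaned label sequence
        labels = [raw[0]] + [b for a, b in zip(raw, raw[1:]) if b != a]
        tm = tm_from_labels(labels, m=6)
        assert tm.n_transitions == len(labels) - 1


class TestDensity:
    def test_back_and_forth(self):
        assert matrix_density(tm_from_labels([1, 2, 1], m=10)) == pytest.approx(0.02)

    def test_all_pairs_visited(self):
        pairs = [(i, j) for i in range(1, 11) for j in range(1, 11) if i != j]
        assert matrix_density(transition_matrix(pairs, m=10)) == pytest.approx(0.9)

    def test_empty(self):
        assert matrix_density(transition_matrix([], m=10)) == 0.0


class TestStationary:
    def test_dwell_proportions(self):
        p = stationary_distribution([1, 2, 1, 3, 1, 2, 1, 3], m=3)
        assert p.tolist() == pytest.approx([0.5, 0.25, 0.25])

    def test_eigenvector_alternation(self):
        p = stationary_distribution([1, 2] * 10, m=2, mode="eigenvector")
        assert p.tolist() == pytest.approx([0.5, 0.5])

    def test_eigenvector_uniform_chain_matches_power_iteration(self):
        # every off-diagonal pair visited once: uniform conditionals
        labels = []
        rng = np.random.default_rng(11)
        state = 1
        labels.append(state)
        for _ in range(20000):
            state = int(rng.choice([s for s in range(1, 11) if s != state]))
            labels.append(state)
        p = stationary_distribution(labels, m=10, mode="eigenvector")
        # oracle: power iteration on the same empirical matrix
        tm = tm_from_labels(labels, m=10)
        v = np.full(10, 0.1)
        for _ in range(500):
            v = v @ tm.probabilities
        assert p == pytest.approx(v, abs=1e-9)
        assert p == pytest.approx(np.full(10, 0.1), abs=0.02)

    def test_reducible_chain_names_unreachable_aois(self):
        # {1, 2, 5} is a communicating class; {3, 4} is absorbing
        labels = [1, 2, 5, 1, 2, 5, 1, 3, 4, 3, 4]
        with pytest.raises(DegenerateInputError, match=r"\[3, 4\]"):
            stationary_distribution(labels, m=5, mode="eigenvector")


class TestGTE:
    def test_deterministic_alternation_is_zero(self):
        labels = [1, 2] * 8
        tm = tm_from_labels(labels, m=2)
        p = stationary_distribution(labels, m=2)
        assert gaze_transition_entropy(tm, p) == 0.0

    def test_hand_evaluated_half_bit(self):
        # only source AOI 1 is uncertain (1->2, 1->3 equally likely): its
        # entropy is 1 bit, stationary weight 0.5 -> GTE = 0.5 bit
        labels = [1, 2, 1, 3, 1, 2, 1, 3]
        tm = tm_from_labels(labels, m=3)
        p = stationary_distribution(labels, m=3)
        assert gaze_transition_entropy(tm, p) == pytest.approx(0.5)

    def test_uniform_chain_reaches_log2_m_minus_1(self):
        pairs = [(i, j) for i in range(1, 11) for j in range(1, 11) if i != j]
        tm = transition_matrix(pairs, m=10)
        p = np.full(10, 0.1)
        assert gaze_transition_entropy(tm, p) == pytest.approx(np.log2(9))

    def test_dimension_mismatch_rejected(self):
        tm = transition_matrix([(1, 2)], m=3)
        with pytest.raises(InputError):
            gaze_transition_entropy(tm, np.array([0.5, 0.5]))

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.integers(1, 5), min_size=2, max_size=100))
    def test_bounded_by_uniform_entropy(self, raw):
        labels = [raw[0]] + [b for a, b in zip(raw, raw[1:]) if b != a]
        if len(labels) < 2:
            return
        m = 5
        tm = tm_from_labels(labels, m)
        p = stationary_distribution(labels, m)
        gte = gaze_transition_entropy(tm, p)
        assert -1e-12 <= gte <= np.log2(m - 1) + 1e-12


class TestScanningStatistics:
    def test_basic_arithmetic(self):
        stats = scanning_statistics(make_sequence([1, 2], durations=[1.0, 2.0]))
        assert stats.n_dwells == 2
        assert stats.mean_dwell_time == pytest.approx(1.5)
        assert stats.aoi_time_share[2] == pytest.approx(2 / 3)

    def test_full_coverage_has_zero_outside_share(self):
        stats = scanning_statistics(
            make_sequence([1], durations=[5.0]), stream_duration=5.0
        )
        assert stats.outside_share == pytest.approx(0.0)

    def test_shares_and_outside_sum_to_one(self):
        stats = scanning_statistics(
            make_sequence([1, 2, 1], durations=[1.0, 2.0, 1.0]),
            stream_duration=10.0,
        )
        total = sum(stats.aoi_time_share.values()) + stats.outside_share
        assert total == pytest.approx(1.0)
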