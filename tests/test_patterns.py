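"""Lempel-Ziv complexity and n-gram mining."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aoiscan import (
    InputError,
    common_ngrams,
    lempel_ziv_complexity,
    ngram_counts,
    ngram_frequency_table,
    unique_aoi_ngrams,
)


def lzc_oracle(symbols):
    """Independent re-implementation: explicit phrase list, linear search."""
    phrases = []
    start = 0
    n = len(symbols)
    count = 0
    while start < n:
        end = start + 1
        while end <= n and list(symbols[start:end]) in phrases:
            end += 1
        phrases.append(list(symbols[start : min(end, n)]))
        count += 1
        start = end
    return count


class TestLZC:
    def test_binary_reference_string(self):
        # parses as 1|0|10|01|010|0101|11 -> 7 phrases
        assert lempel_ziv_complexity("101001010010111") == 7

    def test_single_symbol(self):
        assert lempel_ziv_complexity("a") == 1

    def test_all_distinct_symbols(self):
        assert lempel_ziv_complexity([1, 4, 5, 6]) == 4

    def test_constant_sequences_follow_triangular_growth(self):
        # phrases of a constant run are a, aa, aaa, ...: k complete phrases
        # cover k(k+1)/2 symbols, plus one counted trailing remainder
        for length, expected in [(1, 1), (2, 2), (3, 2), (5, 3), (6, 3), (7, 4)]:
            assert lempel_ziv_complexity("a" * length) == expected

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            lempel_ziv_complexity([])

    @settings(max_examples=150, derandomize=True)
    @given(st.lists(st.integers(1, 4), min_size=1, max_size=80))
    def test_matches_independent_oracle(self, symbols):
        assert lempel_ziv_complexity(symbols) == lzc_oracle(symbols)

    @settings(max_examples=80, derandomize=True)
    @given(st.lists(st.integers(1, 4), min_size=2, max_size=60))
    def test_non_decreasing_under_extension(self, symbols):
        values = [
            lempel_ziv_complexity(symbols[:k]) for k in range(1, len(symbols) + 1)
        ]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestNGrams:
    def test_sliding_window_counts(self):
        table = ngram_counts([1, 4, 5, 1, 4, 5, 1], n=3)
        assert table.entries == {(1, 4, 5): 2, (4, 5, 1): 2, (5, 1, 4): 1}
        assert table.total == 5  # 7 - 3 + 1

    def test_too_short_sequence_warns_empty(self):
        with pytest.warns(UserWarning):
            table = ngram_counts([1, 2], n=3)
        assert len(table) == 0

    def test_bigram_total_equals_transition_count(self):
        labels = [1, 2, 3, 1, 2]
        assert ngram_counts(labels, n=2).total == len(labels) - 1

    @settings(max_examples=80, derandomize=True)
    @given(
        st.lists(st.integers(1, 5), min_size=2, max_size=100),
        st.integers(2, 6),
    )
    def test_total_is_L_minus_n_plus_1(self, labels, n):
        if n > len(labels):
            return
        assert ngram_counts(labels, n).total == len(labels) - n + 1


class TestCommonNGrams:
    A = {(1, 2, 3): 2, (2, 3, 1): 1, (3, 1, 2): 1}
    B = {(3, 1, 2): 1, (1, 2, 3): 1}

    def make(self, entries, n=3):
        from aoiscan import NGramTable

        return NGramTable(n=n, entries=entries)

    def test_intersection_by_hand(self):
        common = common_ngrams([self.make(self.A), self.make(self.B)])
        assert common == {(1, 2, 3), (3, 1, 2)}
        assert len(common) == 2

    def test_identical_members(self):
        common = common_ngrams([self.make(self.A)] * 3)
        assert len(common) == len(self.A)

    def test_disjoint_members(self):
        common = common_ngrams(
            [self.make({(1, 2, 3): 1}), self.make({(4, 5, 6): 2})]
        )
        assert len(common) == 0

    def test_order_invariant(self):
        tables = [self.make(self.A), self.make(self.B), self.make({(1, 2, 3): 9})]
        assert common_ngrams(tables) == common_ngrams(tables[::-1])

    def test_partial_support(self):
        tables = [self.make(self.A), self.make(self.B), self.make({(9, 9, 8): 1})]
        assert common_ngrams(tables, support=1.0) == frozenset()
        assert (1, 2, 3) in common_ngrams(tables, support=2 / 3)

    def test_mixed_n_rejected(self):
        with pytest.raises(InputError):
            common_ngrams([self.make(self.A), self.make({(1, 2): 1}, n=2)])


class TestUniqueAoiNGrams:
    def test_filters_repeats(self):
        from aoiscan import NGramTable

        table = NGramTable(
            n=3, entries={("OTW", "VS", "OTW"): 6, ("OTW", "VS", "ATT"): 2}
        )
        assert unique_aoi_ngrams(table).entries == {("OTW", "VS", "ATT"): 2}

    def test_all_repeats_empty(self):
        from aoiscan import NGramTable

        table = NGramTable(n=3, entries={(1, 2, 1): 3, (2, 2, 2): 1})
        assert len(unique_aoi_ngrams(table)) == 0

    def test_already_unique_unchanged(self):
        from aoiscan import NGramTable

        table = NGramTable(n=3, entries={(1, 2, 3): 4})
        assert unique_aoi_ngrams(table).entries == table.entries


def test_ngram_frequency_table_ranks_and_labels():
    from aoiscan import NGramTable

    tables = [
        NGramTable(n=2, entries={(1, 10): 4, (10, 1): 1}),
        NGramTable(n=2, entries={(1, 10): 2}),
    ]
    labels = ["ATT", "SPD", "VS", "FMA", "HDG", "ND", "NDz", "FCU", "ECAM", "OTW"]
    df = ngram_frequency_table(tables, labels=labels)
    assert df.iloc[0]["ngram"] == "ATT->OTW"
    assert df.iloc[0]["mean_occurrences"] == pytest.approx(3.0)
    assert df.iloc[0]["member_support"] == pytest.approx(1.0)
    assert df.iloc[1]["member_support"] == pytest.approx(0.5)
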