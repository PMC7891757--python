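"""Feature construction, PCA reduction, cosine KNN CV, chance level."""

import numpy as np
import pytest
from scipy import stats

from aoiscan import (
    FeatureTable,
    InputError,
    StratificationError,
    binomial_chance_level,
    build_feature_table,
    crossvalidated_knn,
    make_profile,
    reduce_dimensions,
    simulate_aoi_chain,
    transition_matrix,
)


def matrices_from_profiles(profiles, n_each, n_transitions, seed):
    rng = np.random.default_rng(seed)
    mats, labels = [], []
    for prof in profiles:
        for _ in range(n_each):
            chain = simulate_aoi_chain(
                prof.transition_matrix, n_transitions + 1, int(rng.integers(2**31))
            )
            mats.append(transition_matrix(list(zip(chain[:-1], chain[1:])), prof.m))
            labels.append(prof.name)
    return mats, labels


class TestFeatureTable:
    def test_32_recordings_over_10_aois_give_100_features(self):
        mats, labels = matrices_from_profiles(
            [make_profile("expert-like"), make_profile("novice-like")],
            16, 200, seed=0,
        )
        table = build_feature_table(mats, labels)
        assert table.X.shape == (32, 100)
        assert np.all((table.X >= 0) & (table.X <= 1))

    def test_alternation_matrix_flattens_to_two_unit_cells(self):
        tm = transition_matrix([(1, 2), (2, 1)], m=10)
        table = build_feature_table([tm], ["x"])
        # row-major: feature (i-1)*m + (j-1)
        assert table.X[0, 0 * 10 + 1] == 1.0
        assert table.X[0, 1 * 10 + 0] == 1.0
        assert table.X.sum() == 2.0

    def test_empty_and_mixed_m_rejected(self):
        with pytest.raises(InputError):
            build_feature_table([], [])
        with pytest.raises(InputError):
            build_feature_table(
                [transition_matrix([], 3), transition_matrix([], 4)], ["a", "b"]
            )


class TestReduceDimensions:
    def test_requested_35_capped_to_rank_with_warning(self):
        rng = np.random.default_rng(1)
        table = FeatureTable(X=rng.random((32, 100)), y=np.repeat([0, 1], 16))
        with pytest.warns(UserWarning, match="31"):
            reduced = reduce_dimensions(table, n_components=35)
        assert reduced.n_features == 31

    def test_single_varying_feature_needs_one_component(self):
        X = np.zeros((10, 5))
        X[:, 2] = np.arange(10)
        reduced = reduce_dimensions(FeatureTable(X=X, y=np.zeros(10)), 3)
        # all variance on the first component
        assert np.var(reduced.X[:, 0]) > 0
        assert np.allclose(reduced.X[:, 1:], 0, atol=1e-9)

    def test_zero_components_rejected(self):
        with pytest.raises(InputError):
            reduce_dimensions(FeatureTable(X=np.eye(4), y=np.zeros(4)), 0)


class TestCrossvalidatedKNN:
    def test_separated_profiles_beat_chance(self):
        mats, labels = matrices_from_profiles(
            [make_profile("expert-like"), make_profile("novice-like")],
            16, 220, seed=3,
        )
        report = crossvalidated_knn(build_feature_table(mats, labels), seed=3)
        assert report.overall_accuracy > report.chance_level

    def test_identical_profiles_sit_at_chance(self):
        prof_a = make_profile("expert-like")
        prof_b = make_profile("expert-like", name="expert-b")
        mats, labels = matrices_from_profiles([prof_a, prof_b], 16, 220, seed=5)
        report = crossvalidated_knn(build_feature_table(mats, labels), seed=5)
        half_width = 1.96 * np.sqrt(0.25 / 32)
        assert 0.5 - half_width <= report.overall_accuracy <= 0.5 + half_width

    def test_confusion_accounting(self):
        mats, labels = matrices_from_profiles(
            [make_profile("expert-like"), make_profile("novice-like")],
            16, 220, seed=7,
        )
        report = crossvalidated_knn(build_feature_table(mats, labels), seed=7)
        assert report.confusion.sum() == 32
        assert np.all(report.confusion.sum(axis=1) == 16)
        assert report.overall_accuracy == pytest.approx(
            np.trace(report.confusion) / 32
        )

    def test_reproducible_given_seed(self):
        mats, labels = matrices_from_profiles(
            [make_profile("expert-like"), make_profile("novice-like")],
            16, 220, seed=9,
        )
        table = build_feature_table(mats, labels)
        r1 = crossvalidated_knn(table, seed=42)
        r2 = crossvalidated_knn(table, seed=42)
        assert r1.fold_accuracies == r2.fold_accuracies
        assert np.array_equal(r1.confusion, r2.confusion)

    def test_cosine_distance_invariant_to_row_rescaling(self):
        mats, labels = matrices_from_profiles(
            [make_profile("expert-like"), make_profile("novice-like")],
            16, 220, seed=11,
        )
        table = build_feature_table(mats, labels)
        scaled = FeatureTable(
            X=table.X * np.linspace(1, 7, table.n_rows)[:, None], y=table.y
        )
        r1 = crossvalidated_knn(table, n_components=None, seed=1)
        r2 = crossvalidated_knn(scaled, n_components=None, seed=1)
        assert np.array_equal(r1.confusion, r2.confusion)

    def test_small_class_rejected(self):
        table = FeatureTable(X=np.random.default_rng(0).random((8, 4)),
                             y=np.array([0] * 6 + [1] * 2))
        with pytest.raises(StratificationError):
            crossvalidated_knn(table, k_folds=5)


class TestChanceLevel:
    def test_exact_value_for_32_samples_two_classes(self):
        assert binomial_chance_level(32, 2, 0.05) == pytest.approx(22 / 32)

    def test_single_sample_needs_perfection(self):
        assert binomial_chance_level(1, 2) == 1.0

    def test_loose_alpha_approaches_guessing_rate(self):
        assert binomial_chance_level(1000, 2, alpha=0.999) == pytest.approx(
            0.5, abs=0.05
        )

    @pytest.mark.parametrize("n,c", [(10, 2), (32, 2), (33, 3), (100, 4)])
    def test_matches_scipy_tail_oracle(self, n, c):
        level = binomial_chance_level(n, c, 0.05)
        k = round(level * n)
        assert stats.binom.sf(k - 1, n, 1 / c) < 0.05
        assert stats.binom.sf(k - 2, n, 1 / c) >= 0.05

    def test_bad_alpha_rejected(self):
        with pytest.raises(InputError):
            binomial_chance_level(10, 2, alpha=1.5)
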