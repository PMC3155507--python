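import pickle

import numpy as np
import pytest

from betaturn.features import SampleSet
from betaturn.model import (
    TrainingConfig,
    cluster_positives,
    fit_first_layer,
    fit_second_layer,
    grid_search,
    load_model,
    meta_features,
    predict,
    sample_negatives,
    save_model,
    train_clustered_model,
    train_two_layer,
)


def _blobs(n_per=20, separation=10.0, sd=1.0, d=4, seed=0):
    rng = np.random.default_rng(seed)
    c1 = np.zeros(d)
    c2 = np.zeros(d) + separation * sd / np.sqrt(d)
    a = c1 + sd * rng.normal(size=(n_per, d))
    b = c2 + sd * rng.normal(size=(n_per, d))
    return np.vstack([a, b]), np.repeat([0, 1], n_per)


def _separable_samples(n=40, seed=0):
    rng = np.random.default_rng(seed)
    pos = 0.8 + 0.05 * rng.normal(size=(n // 4, 3))
    neg = 0.2 + 0.05 * rng.normal(size=(n - n // 4, 3))
    X = np.clip(np.vstack([pos, neg]), 0, 1)
    y = np.array([True] * (n // 4) + [False] * (n - n // 4))
    return SampleSet(X=X, y=y, chain_ids=["c"] * n, starts=np.zeros(n, dtype=int))


class TestClusterPositives:
    def test_planted_blobs_recovered(self):
        X, planted = _blobs()
        assignments, _ = cluster_positives(X, k=2, seed=0)
        agree = max(np.mean(assignments == planted), np.mean(assignments == 1 - planted))
        assert agree == 1.0

    def test_k1_center_is_mean(self):
        X, _ = _blobs(n_per=10)
        assignments, centers = cluster_positives(X, k=1, seed=0)
        assert set(assignments) == {0}
        np.testing.assert_allclose(centers[0], X.mean(axis=0), atol=1e-8)

    def test_same_seed_identical(self):
        X, _ = _blobs(seed=3)
        a1, _ = cluster_positives(X, seed=5)
        a2, _ = cluster_positives(X, seed=5)
        np.testing.assert_array_equal(a1, a2)

    def test_larger_cluster_numbered_first(self):
        rng = np.random.default_rng(0)
        big = rng.normal(size=(30, 2))
        small = 50 + rng.normal(size=(10, 2))
        assignments, _ = cluster_positives(np.vstack([big, small]), seed=0)
        assert np.mean(assignments[:30] == 0) == 1.0

    def test_fewer_positives_than_k_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            cluster_positives(np.zeros((1, 3)), k=2)


class TestSampleNegatives:
    def test_three_to_one_ratio(self):
        pool = np.arange(100).reshape(100, 1)
        subset, idx = sample_negatives(pool, 10, ratio=3.0, seed=0)
        assert len(subset) == 30
        assert len(np.unique(idx)) == 30

    def test_whole_pool_when_exact(self):
        pool = np.arange(10).reshape(10, 1)
        subset, _ = sample_negatives(pool, 10, ratio=1.0, seed=0)
        assert len(subset) == 10

    def test_small_pool_warns_and_uses_all(self):
        pool = np.arange(5).reshape(5, 1)
        with pytest.warns(UserWarning, match="whole pool"):
            subset, _ = sample_negatives(pool, 10, ratio=3.0, seed=0)
        assert len(subset) == 5

    def test_deterministic_under_seed(self):
        pool = np.arange(100).reshape(100, 1)
        _, i1 = sample_negatives(pool, 10, seed=4)
        _, i2 = sample_negatives(pool, 10, seed=4)
        _, i3 = sample_negatives(pool, 10, seed=5)
        np.testing.assert_array_equal(i1, i2)
        assert not np.array_equal(i1, i3)

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError, match="empty"):
            sample_negatives(np.zeros((0, 3)), 5)


class TestClusteredModel:
    def test_separable_toy_is_fit_exactly(self):
        pos = np.array([[2.0, 2.0], [2.1, 2.0], [2.0, 2.1], [2.1, 2.1]])
        neg = -pos
        m = train_clustered_model(pos, neg, C=0.5, gamma=0.5, seed=0)
        assert (m.classifier.predict(np.vstack([pos, neg])) == [1] * 4 + [0] * 4).all()

    def test_probabilities_sum_to_one(self):
        pos, neg = np.random.default_rng(0).normal(size=(2, 20, 3))
        m = train_clustered_model(pos, neg + 3, C=1.0, gamma=0.1, seed=0)
        probs = m.predict_proba_pairs(np.random.default_rng(1).normal(size=(50, 3)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert probs.min() >= 0 and probs.max() <= 1

    def test_single_class_input_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            train_clustered_model(np.zeros((0, 2)), np.ones((3, 2)), C=1, gamma=1)


class TestMetaFeatures:
    def test_pairwise_probability_structure(self, tiny_world):
        samples, _, _ = tiny_world
        cfg = TrainingConfig(seed=0)
        m1, m2 = fit_first_layer(samples.X, samples.y, cfg)
        meta = meta_features(samples.X[:50], m1, m2)
        assert meta.shape == (50, 4)
        np.testing.assert_allclose(meta[:, 0] + meta[:, 1], 1.0, atol=1e-9)
        np.testing.assert_allclose(meta[:, 2] + meta[:, 3], 1.0, atol=1e-9)

    def test_training_positive_scores_high_on_own_model(self):
        pos = np.array([[2.0, 2.0], [2.1, 2.0], [2.0, 2.1], [2.1, 2.1], [1.9, 2.0]])
        neg = -pos
        m = train_clustered_model(pos, neg, C=1.0, gamma=0.5, seed=0)
        assert m.predict_proba_pairs(pos[:1])[0, 0] > 0.5

    def test_dimension_mismatch_errors(self, tiny_world):
        samples, _, _ = tiny_world
        m1, m2 = fit_first_layer(samples.X, samples.y, TrainingConfig(seed=0))
        with pytest.raises(ValueError, match="width"):
            meta_features(np.zeros((3, 5)), m1, m2)


class TestTwoLayerTraining:
    def test_first_layer_frozen_across_second_layer_training(self, tiny_world):
        samples, _, _ = tiny_world
        cfg = TrainingConfig(seed=2)
        m1, m2 = fit_first_layer(samples.X, samples.y, cfg)
        before = (pickle.dumps(m1.classifier), pickle.dumps(m2.classifier))
        meta = meta_features(samples.X, m1, m2)
        fit_second_layer(meta, samples.y, cfg)
        after = (pickle.dumps(m1.classifier), pickle.dumps(m2.classifier))
        assert before == after

    def test_smoke_on_twenty_samples(self):
        samples = _separable_samples(n=20, seed=1)
        model = train_two_layer(samples, TrainingConfig(seed=1))
        labels, scores = predict(model, samples)
        assert len(labels) == 20

    def test_separable_fixture_predicted_exactly(self):
        samples = _separable_samples(n=60, seed=2)
        model = train_two_layer(samples, TrainingConfig(seed=2))
        labels, _ = predict(model, samples)
        np.testing.assert_array_equal(labels, samples.y)

    def test_end_to_end_determinism(self, tiny_world):
        samples, _, _ = tiny_world
        scores = []
        for _ in range(2):
            model = train_two_layer(samples, TrainingConfig(seed=9))
            _, s = predict(model, samples)
            scores.append(s)
        np.testing.assert_array_equal(scores[0], scores[1])

    def test_default_hyperparameters_used_without_grid_search(self, tiny_world):
        samples, _, _ = tiny_world
        model = train_two_layer(samples, TrainingConfig(seed=0, grid_search=False))
        for cm in model.cluster_models:
            assert cm.classifier.C == 0.5
            assert cm.classifier.gamma == 0.0078125
        assert model.second_layer.C == 32
        assert model.second_layer.gamma == 8


class TestPredict:
    def test_scores_in_unit_interval(self, tiny_world):
        samples, _, _ = tiny_world
        model = train_two_layer(samples, TrainingConfig(seed=0))
        _, scores = predict(model, samples)
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_label_flips_exactly_at_threshold(self, tiny_world):
        samples, _, _ = tiny_world
        model = train_two_layer(samples, TrainingConfig(seed=0))
        _, scores = predict(model, samples)
        t = float(scores[0])
        labels_at, _ = predict(model, samples, threshold=t)
        assert labels_at[0]
        labels_above, _ = predict(model, samples, threshold=t + 1e-9)
        assert not labels_above[0]

    def test_scheme_mismatch_errors(self, tiny_world):
        from betaturn.features import EncodingScheme

        samples, _, _ = tiny_world
        model = train_two_layer(samples, TrainingConfig(seed=0))
        model.scheme = EncodingScheme()
        with pytest.raises(ValueError, match="scheme"):
            predict(model, samples)


class TestGridSearch:
    def test_singleton_grid_returned(self):
        X, y = _blobs(n_per=15, seed=1)
        assert grid_search(X, y, [2.0], [0.5], seed=0) == (2.0, 0.5)

    def test_tie_prefers_smallest_c_then_gamma(self):
        # perfectly separable: many pairs reach accuracy 1; smallest must win
        X, y = _blobs(n_per=15, separation=30.0, seed=2)
        C, gamma = grid_search(X, y, [1.0, 4.0], [0.1, 0.5], seed=0)
        assert (C, gamma) == (1.0, 0.1)

    def test_deterministic(self):
        X, y = _blobs(n_per=15, seed=3)
        r1 = grid_search(X, y, [0.5, 2.0], [0.1, 1.0], seed=7)
        r2 = grid_search(X, y, [0.5, 2.0], [0.1, 1.0], seed=7)
        assert r1 == r2

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            grid_search(np.zeros((4, 2)), np.array([0, 1, 0, 1]), [], [1.0])


class TestPersistence:
    def test_save_load_round_trip_predicts_identically(self, tiny_world, tmp_path):
        samples, _, _ = tiny_world
        model = train_two_layer(samples, TrainingConfig(seed=0))
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        _, s1 = predict(model, samples)
        _, s2 = predict(back, samples)
        np.testing.assert_array_equal(s1, s2)
        assert back.config == model.config

    def test_unknown_archive_version_rejected(self, tmp_path):
        import joblib

        path = tmp_path / "bad.joblib"
        joblib.dump({"format_version": 99}, path)
        with pytest.raises(ValueError, match="version"):
            load_model(path)
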