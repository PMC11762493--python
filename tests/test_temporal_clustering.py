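"""Clustering-layer math: similarity, assignments, targets, KL, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtcgait.temporal_autoencoder import TAE, TAEConfig
from dtcgait.temporal_clustering import (
    Centroids,
    DTCConfig,
    init_centroids,
    kl_divergence,
    pearson_similarity,
    soft_assign,
    target_distribution,
    train,
)


def _rand_rowstoch(rng, n, k):
    q = rng.uniform(0.01, 1.0, size=(n, k))
    return q / q.sum(axis=1, keepdims=True)


class TestPearsonSimilarity:
    def test_identical_vectors_give_zero(self, rng):
        z = rng.normal(size=10)
        assert pearson_similarity(z, z) == pytest.approx(0.0, abs=1e-12)

    def test_negated_vector_gives_four(self, rng):
        z = rng.normal(size=10)
        assert pearson_similarity(z, -z + 3.0) == pytest.approx(4.0, abs=1e-12)

    def test_hand_example(self):
        # rho((1,2,3,4),(1,3,2,4)) = 0.8 -> 2(1-rho) = 0.4
        assert pearson_similarity([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.4)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(100):
            z, c = rng.normal(size=8), rng.normal(size=8)
            s = pearson_similarity(z, c)
            assert s == pytest.approx(pearson_similarity(c, z), abs=1e-12)
            assert 0.0 <= s <= 4.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_similarity(np.ones(5), np.arange(5.0))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            z, c = rng.normal(size=12), rng.normal(size=12)
            rho = float(np.corrcoef(z, c)[0, 1])
            assert pearson_similarity(z, c) == pytest.approx(2 * (1 - rho), abs=1e-9)


class TestSoftAssign:
    def test_single_cluster_is_all_ones(self, rng):
        Z = rng.normal(size=(5, 6))
        C = rng.normal(size=(1, 6))
        assert np.allclose(soft_assign(Z, C), 1.0, atol=1e-12)

    def test_student_t_weighting_hand_example(self, rng):
        # similarities (0, 2) -> weights (1, 1/3) -> q = (0.75, 0.25)
        z = rng.normal(size=8)
        c0 = z.copy()  # similarity 0
        # construct c1 with rho = 0: orthogonal after centering
        zc = z - z.mean()
        c1 = rng.normal(size=8)
        c1 -= c1.mean()
        c1 -= (c1 @ zc) / (zc @ zc) * zc  # similarity = 2(1-0) = 2
        Q = soft_assign(z[None, :], np.vstack([c0, c1]))
        assert Q[0] == pytest.approx([0.75, 0.25], abs=1e-9)

    def test_equal_similarities_give_uniform_row(self, rng):
        z = rng.normal(size=6)
        C = np.vstack([z, z, z])
        assert np.allclose(soft_assign(z[None, :], C), 1.0 / 3.0, atol=1e-12)

    def test_rows_sum_to_one(self, rng):
        Q = soft_assign(rng.normal(size=(20, 9)), rng.normal(size=(4, 9)))
        assert np.allclose(Q.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(Q > 0)

    def test_oracle_per_entry(self, rng):
        Z, C = rng.normal(size=(10, 7)), rng.normal(size=(3, 7))
        Q = soft_assign(Z, C)
        for i in range(10):
            w = np.array(
                [1.0 / (1.0 + pearson_similarity(Z[i], C[j])) for j in range(3)]
            )
            assert Q[i] == pytest.approx(w / w.sum(), abs=1e-9)


class TestTargetDistribution:
    def test_hand_example(self):
        Q = np.array([[0.75, 0.25], [0.25, 0.75]])
        P, f = target_distribution(Q)
        assert f == pytest.approx([1.0, 1.0])
        assert np.allclose(P, [[0.9, 0.1], [0.1, 0.9]], atol=1e-12)

    def test_one_hot_fixed_point(self):
        Q = np.eye(3)[[0, 1, 2, 0]]
        P, _ = target_distribution(Q)
        assert np.allclose(P, Q, atol=1e-12)

    def test_uniform_fixed_point(self):
        Q = np.full((6, 4), 0.25)
        P, _ = target_distribution(Q)
        assert np.allclose(P, Q, atol=1e-12)

    def test_frequency_equals_column_sum_and_rows_stochastic(self, rng):
        Q = _rand_rowstoch(rng, 30, 5)
        P, f = target_distribution(Q)
        assert np.allclose(f, Q.sum(axis=0), atol=1e-9)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_brute_force_oracle(self, rng):
        Q = _rand_rowstoch(rng, 12, 4)
        P, _ = target_distribution(Q)
        f = Q.sum(axis=0)
        for i in range(12):
            w = Q[i] ** 2 / f
            assert P[i] == pytest.approx(w / w.sum(), abs=1e-12)


class TestKLDivergence:
    def test_identity_is_zero(self, rng):
        Q = _rand_rowstoch(rng, 5, 3)
        assert kl_divergence(Q, Q) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_vs_uniform_is_log2(self):
        assert kl_divergence([[1.0, 0.0]], [[0.5, 0.5]]) == pytest.approx(
            np.log(2.0), abs=1e-12
        )

    def test_matches_double_loop_oracle_and_nonnegative(self, rng):
        for _ in range(100):
            P = _rand_rowstoch(rng, 10, 4)
            Q = _rand_rowstoch(rng, 10, 4)
            expect = sum(
                P[i, j] * np.log(P[i, j] / Q[i, j])
                for i in range(10)
                for j in range(4)
            )
            got = kl_divergence(P, Q)
            assert got == pytest.approx(expect, abs=1e-12)
            assert got >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(np.ones((2, 2)) / 2, np.ones((2, 3)) / 3)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_kl_nonnegative_and_zero_iff_equal(seed):
    rng = np.random.default_rng(seed)
    P = _rand_rowstoch(rng, 6, 3)
    Q = _rand_rowstoch(rng, 6, 3)
    kl = kl_divergence(P, Q)
    assert kl >= 0.0
    if np.abs(P - Q).max() < 1e-12:
        assert kl == pytest.approx(0.0, abs=1e-10)
    if kl < 1e-14:
        assert np.abs(P - Q).max() < 1e-6


class TestInitCentroids:
    def test_K_equals_N_gives_singletons(self, rng):
        lat = rng.normal(size=(5, 4))
        cents, labels = init_centroids(lat, 5)
        # every centroid is exactly one latent vector
        for row in cents.values:
            assert np.any(np.all(np.isclose(lat, row, atol=1e-12), axis=1))
        assert len(np.unique(labels)) == 5

    def test_two_far_blobs_recovered(self, rng):
        a = rng.normal(scale=1e-3, size=(10, 3))
        b = rng.normal(scale=1e-3, size=(12, 3)) + 1e3
        lat = np.vstack([a, b])
        cents, labels = init_centroids(lat, 2)
        means = sorted([a.mean(axis=0)[0], b.mean(axis=0)[0]])
        got = sorted(cents.values[:, 0])
        assert got == pytest.approx(means, abs=1e-6)
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1

    def test_deterministic(self, rng):
        lat = rng.normal(size=(20, 6))
        c1, l1 = init_centroids(lat, 4)
        c2, l2 = init_centroids(lat, 4)
        assert np.array_equal(c1.values, c2.values)
        assert np.array_equal(l1, l2)

    def test_fewer_points_than_K_rejected(self, rng):
        with pytest.raises(ValueError):
            init_centroids(rng.normal(size=(3, 2)), 4)


class TestTrain:
    def test_zero_learning_rates_freeze_init_assignment(self, rng):
        rows = rng.normal(size=(20, 60))
        cfg = TAEConfig(kernel_size=5, pool_size=5, conv_channels=6, hidden1=6,
                        hidden2=2, pretrain_epochs=1, batch_size=20, seed=0)
        model = TAE(cfg, 60)
        lat = model.latent_matrix(rows)
        cents, _ = init_centroids(lat, 3)
        expected = np.argmax(soft_assign(lat, cents), axis=1)
        res = train(rows, model,
                    DTCConfig(K=3, epochs=3, tae_lr=0.0, cluster_lr=0.0, seed=0))
        assert np.array_equal(res.labels, expected)
        assert len(res.history) == 3

    def test_history_and_contracts_during_short_run(self, rng):
        rows = rng.normal(size=(15, 40))
        cfg = TAEConfig(kernel_size=5, pool_size=4, conv_channels=5, hidden1=5,
                        hidden2=1, pretrain_epochs=1, batch_size=15, seed=1)
        model = TAE(cfg, 40)
        sums = []
        res = train(rows, model, DTCConfig(K=3, epochs=5, seed=1),
                    epoch_callback=lambda e, Q, P: sums.append(
                        (Q.sum(axis=1), P.sum(axis=1))))
        assert len(res.history) == 5
        for qs, ps in sums:
            assert np.allclose(qs, 1.0, atol=1e-9)
            assert np.allclose(ps, 1.0, atol=1e-9)
        # loss components: total = mse + kl, kl >= 0
        for total, mse, kl in res.history:
            assert total == pytest.approx(mse + kl, abs=1e-9)
            assert kl >= 0.0

    def test_epochs_default_is_600(self):
        assert DTCConfig(K=4).epochs == 600

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            DTCConfig(K=1)
        with pytest.raises(ValueError):
            DTCConfig(K=3, epochs=0)


def test_centroids_validation():
    with pytest.raises(ValueError):
        Centroids(np.array([[np.nan, 1.0]]))
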