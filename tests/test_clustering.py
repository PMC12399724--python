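"""Student-t soft assignment, target distribution, KL divergence, K-Means
and DEC refinement."""

import numpy as np
import pytest

import harclust as h
from harclust.clustering import (Centroids, dec_build_autoencoder, dec_fit,
                                 dec_layer_widths, kl_divergence,
                                 kl_soft_assign_grads, kmeans_fit,
                                 soft_assign, target_distribution)


class TestSoftAssign:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        Q = soft_assign(rng.normal(size=(20, 3)), rng.normal(size=(4, 3))).Q
        assert np.allclose(Q.sum(axis=1), 1.0)
        assert (Q > 0).all() and (Q < 1).all()

    def test_point_at_centroid_dominates(self):
        mu = np.array([[0.0, 0.0], [50.0, 50.0], [-50.0, 50.0]])
        Q = soft_assign(np.array([[0.0, 0.0]]), mu, alpha=1.0).Q
        assert Q[0, 0] > 0.99

    def test_equidistant_symmetry(self):
        mu = np.array([[-1.0], [1.0]])
        Q = soft_assign(np.array([[0.0]]), mu, alpha=1.0).Q
        assert np.allclose(Q[0], [0.5, 0.5])
        Q2 = soft_assign(np.array([[0.5]]), np.array([[0.0], [1.0]]), 1.0).Q
        assert np.allclose(Q2[0], [0.5, 0.5])

    def test_identical_centroids_give_uniform(self):
        mu = np.zeros((3, 2))
        Q = soft_assign(np.random.default_rng(0).normal(size=(5, 2)), mu).Q
        assert np.allclose(Q, 1.0 / 3.0)

    def test_large_alpha_approaches_gaussian_kernel(self):
        rng = np.random.default_rng(0)
        Z, mu = rng.normal(size=(10, 2)), rng.normal(size=(3, 2))
        Q = soft_assign(Z, mu, alpha=1e6).Q
        d2 = ((Z[:, None] - mu[None]) ** 2).sum(-1)
        g = np.exp(-d2 / 2)
        g /= g.sum(axis=1, keepdims=True)
        assert np.allclose(Q, g, atol=1e-4)

    def test_non_positive_alpha_rejected(self):
        with pytest.raises(ValueError):
            soft_assign(np.zeros((2, 2)), np.zeros((2, 2)), alpha=0.0)


class TestTargetDistribution:
    def test_uniform_is_fixed_point(self):
        Q = np.full((6, 3), 1.0 / 3.0)
        assert np.allclose(target_distribution(Q).P, Q)

    def test_one_hot_is_fixed_point(self):
        Q = np.eye(3)[[0, 1, 2, 0]]
        assert np.allclose(target_distribution(Q).P, Q)

    def test_sharpening_with_balanced_frequencies(self):
        # two mirrored rows make cluster frequencies equal
        Q = np.array([[0.8, 0.2], [0.2, 0.8]])
        P = target_distribution(Q).P
        # direct evaluation: p ∝ q^2 / f with f = (1, 1)
        assert np.isclose(P[0, 0], 0.64 / 0.68)
        assert P[0, 0] > 0.8

    def test_rows_renormalized(self):
        rng = np.random.default_rng(0)
        Q = rng.dirichlet(np.ones(4), size=30)
        assert np.allclose(target_distribution(Q).P.sum(axis=1), 1.0)


class TestKlDivergence:
    def test_identical_distributions_give_zero(self):
        P = np.array([[0.3, 0.7], [0.5, 0.5]])
        assert kl_divergence(P, P) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_vs_uniform_is_ln2(self):
        assert kl_divergence(np.array([[1.0, 0.0]]),
                             np.array([[0.5, 0.5]])) == pytest.approx(np.log(2))

    def test_nonnegative_with_zero_only_at_equality(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            P = rng.dirichlet(np.ones(4), size=5)
            Q = rng.dirichlet(np.ones(4), size=5)
            # brute-force summation oracle
            brute = sum(P[i, j] * np.log(P[i, j] / Q[i, j])
                        for i in range(5) for j in range(4) if P[i, j] > 0)
            val = kl_divergence(P, Q)
            assert val == pytest.approx(brute)
            assert val >= 0.0

    def test_infinite_when_q_lacks_support(self):
        with pytest.warns(UserWarning, match="infinite"):
            v = kl_divergence(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]))
        assert v == np.inf


class TestKMeans:
    def test_separated_blobs_recovered_exactly(self):
        from sklearn.datasets import make_blobs
        X, y = make_blobs(n_samples=300, centers=3, cluster_std=0.05,
                          center_box=(-2, 2), random_state=0)
        res = kmeans_fit(X, k=3, seed=0)
        assert h.ari(y, res.hard_labels) == pytest.approx(1.0)
        assert np.array_equal(res.hard_labels, res.Q.Q.argmax(axis=1))

    def test_k_equals_n_gives_zero_inertia(self):
        X = np.random.default_rng(0).normal(size=(5, 2))
        res = kmeans_fit(X, k=5, seed=0, n_init=10)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_dataset_keeps_centroids(self):
        X = np.random.default_rng(0).normal(size=(40, 3))
        a = kmeans_fit(X, k=3, seed=0)
        b = kmeans_fit(np.vstack([X, X]), k=3, seed=0)
        ca = np.sort(a.centroids.mu, axis=0)
        cb = np.sort(b.centroids.mu, axis=0)
        assert np.allclose(ca, cb, atol=1e-6)

    def test_fewer_points_than_clusters_rejected(self):
        with pytest.raises(ValueError):
            kmeans_fit(np.zeros((2, 2)), k=3)

    def test_estimator_interface(self):
        from sklearn.datasets import make_blobs
        X, y = make_blobs(n_samples=90, centers=3, cluster_std=0.1,
                          random_state=0)
        est = h.StudentTKMeans(n_clusters=3, seed=0).fit(X)
        assert est.labels_.shape == (90,)
        assert est.Q_.shape == (90, 3)
        assert np.array_equal(est.predict(X), est.labels_)


class TestDec:
    def test_autoencoder_widths_mirror_500_500_2000_10(self):
        spec = dec_build_autoencoder(180)
        assert dec_layer_widths(spec) == [180, 500, 500, 2000, 10,
                                          2000, 500, 500, 180]
        assert spec.latent_dim == 10

    def test_max_iter_default_is_20000(self):
        import inspect
        assert inspect.signature(dec_fit).parameters["max_iter"].default == 20000

    def test_tol_one_stops_at_first_target_update(self, latent_blobs):
        X, _ = latent_blobs
        res = dec_fit(X, k=3, pretrain_epochs=2, update_interval=10,
                      tol=1.0, seed=0, hidden=(32,), latent_dim=4)
        assert res.converged and res.n_iter == 10

    def test_invalid_max_iter_rejected(self, latent_blobs):
        with pytest.raises(ValueError):
            dec_fit(latent_blobs[0], k=3, max_iter=0)

    def test_refinement_improves_or_preserves_nmi(self, latent_blobs):
        X, y = latent_blobs
        res = dec_fit(X, k=3, pretrain_epochs=80, update_interval=50,
                      tol=1e-3, seed=0, hidden=(64, 64), latent_dim=5,
                      batch_size=128)
        assert h.nmi(y, res.hard_labels) >= h.nmi(y, res.init_labels)
        assert res.converged and res.n_iter < 20000

    def test_rows_normalized_and_kl_nonnegative_throughout(self, latent_blobs):
        X, _ = latent_blobs
        res = dec_fit(X, k=3, pretrain_epochs=20, update_interval=25,
                      tol=1e-4, max_iter=200, seed=0, hidden=(32,),
                      latent_dim=4, batch_size=128)
        assert np.allclose(res.Q.Q.sum(axis=1), 1.0)
        assert all(v >= 0.0 for v in res.kl_history)

    def test_kl_decreases_within_each_fixed_target_interval(self, latent_blobs):
        X, _ = latent_blobs
        res = dec_fit(X, k=3, pretrain_epochs=80, update_interval=50,
                      tol=1e-3, seed=0, hidden=(64, 64), latent_dim=5,
                      batch_size=128)
        drops = [end - start for start, end in res.kl_intervals]
        assert len(drops) >= 2
        assert np.mean(drops) < 0.0
        assert all(d <= 1e-6 for d in drops)

    def test_gradients_match_finite_differences(self):
        """Frozen-encoder DEC step = KL gradient in (z, mu) — checked
        against central differences on a 5-point, k=2 instance."""
        rng = np.random.default_rng(0)
        Z, mu = rng.standard_normal((5, 3)), rng.standard_normal((2, 3))
        P = target_distribution(soft_assign(Z, mu, 1.0)).P
        dZ, dmu = kl_soft_assign_grads(Z, mu, P, 1.0)
        eps = 1e-6

        def L(Zv, muv):
            return kl_divergence(P, soft_assign(Zv, muv, 1.0).Q)

        for idx in [(0, 0), (2, 1), (4, 2)]:
            Zp, Zm = Z.copy(), Z.copy()
            Zp[idx] += eps
            Zm[idx] -= eps
            assert np.isclose((L(Zp, mu) - L(Zm, mu)) / (2 * eps), dZ[idx],
                              rtol=1e-5, atol=1e-9)
        for idx in [(0, 0), (1, 2)]:
            mp, mm = mu.copy(), mu.copy()
            mp[idx] += eps
            mm[idx] -= eps
            assert np.isclose((L(Z, mp) - L(Z, mm)) / (2 * eps), dmu[idx],
                              rtol=1e-5, atol=1e-9)

    def test_centroids_validate(self):
        with pytest.raises(ValueError):
            Centroids(mu=np.array([[np.inf, 0.0], [0.0, 1.0]]))
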