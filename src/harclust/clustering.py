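"""Phase-2 unsupervised clustering on latent features.

Two methods:

* **Student-t K-Means** — standard Lloyd/k-means++ clustering (via
  scikit-learn) whose converged centroids are scored with a Student-t
  kernel soft assignment: ``q_ij ∝ (1 + ||z_i - mu_j||^2 / alpha)^-((alpha+1)/2)``.
  Optionally the centroids can be re-estimated under the soft
  responsibilities until they stabilize.

* **Deep Embedded Clustering (DEC)** — a dense autoencoder
  (encoder widths 500-500-2000, 10 latent features, mirrored decoder) is
  pretrained with MSE, centroids are initialized by k-means on the
  embeddings, then encoder and centroids are jointly refined by gradient
  descent on the KL divergence ``KL(P||Q) = Σ p log(p/q)`` between the
  soft assignment Q and a sharpened target distribution
  ``p_ij = (q_ij^2 / f_j) / Σ_j' (q_ij'^2 / f_j')`` with cluster
  frequencies ``f_j = Σ_i q_ij``.  Training stops when fewer than ``tol``
  of the hard assignments change between consecutive target updates, or
  at ``max_iter`` (default 20 000) gradient steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from . import nn
from .extractors import LatentFeatures

__all__ = [
    "Centroids", "SoftAssignment", "TargetDistribution", "ClusterResult",
    "soft_assign", "target_distribution", "kl_divergence",
    "kl_soft_assign_grads", "kmeans_fit", "dec_build_autoencoder",
    "dec_layer_widths", "dec_fit", "StudentTKMeans", "DeepEmbeddedClustering",
]


@dataclass
class Centroids:
    mu: np.ndarray  # [k, d]

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.ndim != 2 or self.mu.shape[0] < 2:
            raise ValueError("mu must be [k >= 2, d]")
        if not np.isfinite(self.mu).all():
            raise ValueError("centroids must be finite")


@dataclass
class SoftAssignment:
    Q: np.ndarray   # [n, k], rows sum to 1
    alpha: float = 1.0

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("soft-assignment rows must sum to 1")


@dataclass
class TargetDistribution:
    P: np.ndarray   # [n, k], rows sum to 1

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("target-distribution rows must sum to 1")


@dataclass
class ClusterResult:
    hard_labels: np.ndarray
    Q: SoftAssignment
    centroids: Centroids
    n_iter: int
    converged: bool
    inertia: Optional[float] = None
    kl_history: list = field(default_factory=list)
    kl_intervals: list = field(default_factory=list)   # (start, end) per fixed-P interval
    init_labels: Optional[np.ndarray] = None


def _as_matrix(Z) -> tuple[np.ndarray, Optional[np.ndarray]]:
    if isinstance(Z, LatentFeatures):
        return Z.matrix, Z.source_labels
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 3:  # raw windows: flatten
        Z = Z.reshape(Z.shape[0], -1)
    return Z, None


def soft_assign(Z, centroids, alpha: float = 1.0) -> SoftAssignment:
    """Student-t kernel soft assignment of points to centroids."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    Zm, _ = _as_matrix(Z)
    mu = centroids.mu if isinstance(centroids, Centroids) else np.asarray(centroids, float)
    d2 = ((Zm[:, None, :] - mu[None, :, :]) ** 2).sum(axis=2)
    logq = -((alpha + 1.0) / 2.0) * np.log1p(d2 / alpha)
    logq -= logq.max(axis=1, keepdims=True)
    q = np.exp(logq)
    q /= q.sum(axis=1, keepdims=True)
    return SoftAssignment(Q=q, alpha=alpha)


def target_distribution(Q) -> TargetDistribution:
    """Sharpened target: square Q, normalize by cluster frequency, renormalize."""
    q = Q.Q if isinstance(Q, SoftAssignment) else np.asarray(Q, dtype=float)
    f = q.sum(axis=0)
    w = q**2 / f
    return TargetDistribution(P=w / w.sum(axis=1, keepdims=True))


def kl_divergence(P, Q) -> float:
    """``Σ p log(p / q)`` (natural log) with the convention 0·log(0/q) = 0.

    Returns ``inf`` with a warning if P puts mass where Q has none.
    """
    p = P.P if isinstance(P, TargetDistribution) else np.asarray(P, dtype=float)
    q = Q.Q if isinstance(Q, SoftAssignment) else np.asarray(Q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("P and Q shapes differ")
    mask = p > 0
    if np.any(q[mask] == 0):
        warnings.warn("P has mass where Q is zero; KL divergence is infinite")
        return float("inf")
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def kl_soft_assign_grads(Z, mu, P, alpha: float = 1.0):
    """Analytic gradients of ``KL(P || Q(Z, mu))`` w.r.t. ``Z`` and ``mu``.

    Q is the Student-t soft assignment of Z to mu.  Returns ``(dZ, dmu)``
    for the summed (not averaged) KL.
    """
    Zm, _ = _as_matrix(Z)
    mu = np.asarray(mu, dtype=float)
    q = soft_assign(Zm, mu, alpha).Q
    p = P.P if isinstance(P, TargetDistribution) else np.asarray(P, dtype=float)
    diff = Zm[:, None, :] - mu[None, :, :]             # [n, k, d]
    d2 = (diff**2).sum(axis=2)
    coef = ((alpha + 1.0) / alpha) * (p - q) / (1.0 + d2 / alpha)  # [n, k]
    dZ = (coef[:, :, None] * diff).sum(axis=1)
    dmu = -(coef[:, :, None] * diff).sum(axis=0)
    return dZ, dmu


def kmeans_fit(Z, k: int, n_init: int = 10, seed: int = 0, alpha: float = 1.0,
               soft_update: bool = False, max_soft_iter: int = 100,
               soft_tol: float = 1e-6) -> ClusterResult:
    """K-Means (Lloyd + k-means++, best of ``n_init``) with Student-t
    soft assignment on the converged centroids.

    With ``soft_update=True`` the centroids are additionally re-estimated
    as responsibility-weighted means under Q until they stabilize.
    """
    Zm, _ = _as_matrix(Z)
    n = len(Zm)
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Zm)
    mu = km.cluster_centers_.copy()
    n_iter = int(km.n_iter_)
    if soft_update:
        for _ in range(max_soft_iter):
            q = soft_assign(Zm, mu, alpha).Q
            new_mu = (q.T @ Zm) / q.sum(axis=0)[:, None]
            shift = float(np.abs(new_mu - mu).max())
            mu = new_mu
            n_iter += 1
            if shift < soft_tol:
                break
    Q = soft_assign(Zm, mu, alpha)
    hard = Q.Q.argmax(axis=1)
    inertia = float(((Zm - mu[hard]) ** 2).sum())
    return ClusterResult(hard_labels=hard, Q=Q, centroids=Centroids(mu),
                         n_iter=n_iter, converged=True, inertia=inertia)


# ---------------------------------------------------------------------------
# DEC


def dec_build_autoencoder(input_dim: int, hidden=(500, 500, 2000),
                          latent_dim: int = 10):
    """Spec for the DEC autoencoder: dense encoder ``input -> 500 -> 500
    -> 2000 -> 10`` with a mirrored decoder."""
    from .extractors import build_spec

    return build_spec("mlp_ae", (int(input_dim), 1), n_classes=1,
                      latent_dim=int(latent_dim), hidden=tuple(hidden))


def dec_layer_widths(spec) -> list[int]:
    """Widths along the full autoencoder path (encoder + mirrored decoder)."""
    w, c = spec.input_shape
    d = w * c
    hidden = list(spec.hyperparams["hidden"])
    return [d, *hidden, spec.latent_dim, *hidden[::-1], d]


class _DecNet:
    """Dense autoencoder used by DEC (linear bottleneck, mirrored decoder)."""

    def __init__(self, input_dim, hidden, latent_dim, rng, sigmoid_out):
        enc = nn.Sequential()
        n_in = input_dim
        for wdt in hidden:
            enc.add(nn.Dense(n_in, wdt, rng, activation="relu"))
            n_in = wdt
        enc.add(nn.Dense(n_in, latent_dim, rng))          # linear bottleneck
        dec = nn.Sequential()
        n_in = latent_dim
        for wdt in reversed(hidden):
            dec.add(nn.Dense(n_in, wdt, rng, activation="relu"))
            n_in = wdt
        dec.add(nn.Dense(n_in, input_dim, rng,
                         activation="sigmoid" if sigmoid_out else None))
        self.encoder, self.decoder = enc, dec


def dec_fit(Z_or_raw, k: int, pretrain_epochs: int = 300,
            update_interval: int = 140, tol: float = 1e-3,
            max_iter: int = 20000, seed: int = 0, alpha: float = 1.0,
            batch_size: int = 256, lr: float = 1e-3,
            hidden=(500, 500, 2000), latent_dim: int = 10,
            kmeans_n_init: int = 10) -> ClusterResult:
    """Full DEC schedule: MSE pretraining, k-means initialization, then
    joint KL(P||Q) refinement of encoder and centroids.

    ``Z_or_raw`` may be latent features, a flat data matrix, or raw
    windows (flattened).  The decoder output layer is sigmoid when the
    input lies in [0, 1] and linear otherwise.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    X, _ = _as_matrix(Z_or_raw)
    n, d = X.shape
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    rng = np.random.default_rng(seed)
    net = _DecNet(d, hidden, latent_dim, rng,
                  sigmoid_out=(X.min() >= 0.0 and X.max() <= 1.0))
    enc, dec = net.encoder, net.decoder

    # (1) reconstruction pretraining
    opt = nn.Adam(enc.params + dec.params, enc.grads + dec.grads, lr=lr)
    for _ in range(pretrain_epochs):
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            xb = X[order[i:i + batch_size]]
            recon = dec.forward(enc.forward(xb, training=True), training=True)
            _, dr = nn.mse(recon, xb)
            enc.zero_grad(), dec.zero_grad()
            enc.backward(dec.backward(dr))
            opt.step()

    # (2) centroid initialization by k-means on embeddings
    Z0 = enc.forward(X, training=False)
    km = KMeans(n_clusters=k, n_init=kmeans_n_init, random_state=seed).fit(Z0)
    mu = km.cluster_centers_.copy()
    init_labels = km.labels_.copy()

    # (3) KL refinement of encoder + centroids
    mu_grad = np.zeros_like(mu)
    opt = nn.Adam(enc.params + [mu], enc.grads + [mu_grad], lr=lr)
    kl_history: list[float] = []       # KL against the freshly set P
    kl_intervals: list[tuple] = []     # (start, end) KL against a fixed P
    prev_hard = init_labels
    converged = False
    P = None
    kl_start = None
    it = 0
    while it < max_iter:
        if it % update_interval == 0:
            Z = enc.forward(X, training=False)
            Q = soft_assign(Z, mu, alpha)
            if P is not None:
                kl_intervals.append((kl_start, kl_divergence(P, Q) / n))
            P = target_distribution(Q).P
            kl_start = kl_divergence(P, Q) / n
            kl_history.append(kl_start)
            hard = Q.Q.argmax(axis=1)
            delta = float((hard != prev_hard).mean())
            prev_hard = hard
            if it > 0 and delta < tol:
                converged = True
                break
        idx = rng.integers(0, n, size=min(batch_size, n))
        zb = enc.forward(X[idx], training=True)
        dz, dmu = kl_soft_assign_grads(zb, mu, P[idx], alpha)
        enc.zero_grad()
        mu_grad[...] = dmu / len(idx)
        enc.backward(dz / len(idx))
        opt.step()
        it += 1

    Z = enc.forward(X, training=False)
    Q = soft_assign(Z, mu, alpha)
    hard = Q.Q.argmax(axis=1)
    return ClusterResult(hard_labels=hard, Q=Q, centroids=Centroids(mu),
                         n_iter=it, converged=converged,
                         kl_history=kl_history, init_labels=init_labels,
                         kl_intervals=kl_intervals)


# ---------------------------------------------------------------------------
# sklearn-style estimators


class StudentTKMeans(BaseEstimator, ClusterMixin):
    """K-Means with Student-t soft assignment, sklearn protocol."""

    def __init__(self, n_clusters=6, alpha=1.0, n_init=10, soft_update=False,
                 seed=0):
        self.n_clusters = n_clusters
        self.alpha = alpha
        self.n_init = n_init
        self.soft_update = soft_update
        self.seed = seed

    def fit(self, X, y=None):
        res = kmeans_fit(X, k=self.n_clusters, n_init=self.n_init,
                         seed=self.seed, alpha=self.alpha,
                         soft_update=self.soft_update)
        self.result_ = res
        self.labels_ = res.hard_labels
        self.cluster_centers_ = res.centroids.mu
        self.Q_ = res.Q.Q
        self.inertia_ = res.inertia
        return self

    def predict(self, X):
        Q = soft_assign(X, self.cluster_centers_, self.alpha)
        return Q.Q.argmax(axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class DeepEmbeddedClustering(BaseEstimator, ClusterMixin):
    """DEC with the sklearn protocol (``fit`` then ``labels_`` etc.)."""

    def __init__(self, n_clusters=6, alpha=1.0, pretrain_epochs=300,
                 update_interval=140, tol=1e-3, max_iter=20000,
                 batch_size=256, lr=1e-3, hidden=(500, 500, 2000),
                 latent_dim=10, seed=0):
        self.n_clusters = n_clusters
        self.alpha = alpha
        self.pretrain_epochs = pretrain_epochs
        self.update_interval = update_interval
        self.tol = tol
        self.max_iter = max_iter
        self.batch_size = batch_size
        self.lr = lr
        self.hidden = hidden
        self.latent_dim = latent_dim
        self.seed = seed

    def fit(self, X, y=None):
        res = dec_fit(X, k=self.n_clusters, pretrain_epochs=self.pretrain_epochs,
                      update_interval=self.update_interval, tol=self.tol,
                      max_iter=self.max_iter, seed=self.seed, alpha=self.alpha,
                      batch_size=self.batch_size, lr=self.lr,
                      hidden=self.hidden, latent_dim=self.latent_dim)
        self.result_ = res
        self.labels_ = res.hard_labels
        self.init_labels_ = res.init_labels
        self.cluster_centers_ = res.centroids.mu
        self.Q_ = res.Q.Q
        self.kl_history_ = res.kl_history
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
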