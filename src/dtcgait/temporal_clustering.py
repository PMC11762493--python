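"""Temporal clustering layer and the joint training loop.

Latent gait features are softly assigned to K centroids through a
Student's-t kernel over a Pearson-correlation dissimilarity,

    similarity(z, c) = 2 (1 - rho(z, c))            in [0, 4],
    q_ij = (1 + similarity(z_i, c_j))^-1 / sum_j' (...)^-1,

sharpened into a target distribution

    p_ij = (q_ij^2 / f_j) / sum_j' (q_ij'^2 / f_j'),   f_j = sum_i q_ij,

and trained by minimizing  J_total = J_MSE + J_KL  where
J_KL = sum_ij p_ij log(p_ij / q_ij).  Centroids are initialized from
complete-linkage agglomerative clustering of the pretrained latents and
are themselves gradient-updated, at a (much smaller) separate learning
rate from the autoencoder weights.  The target distribution is treated as
a constant between refreshes, the usual convention for this loss family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import AgglomerativeClustering

from ._autodiff import Var
from .gait_io import GaitTensor
from .temporal_autoencoder import TAE, TAEConfig, _mse_var

logger = logging.getLogger(__name__)

__all__ = [
    "DTCConfig",
    "Centroids",
    "pearson_similarity",
    "init_centroids",
    "soft_assign",
    "target_distribution",
    "kl_divergence",
    "train",
    "TrainResult",
]


@dataclass
class DTCConfig:
    K: int = 7
    epochs: int = 600
    tae_lr: float = 0.001
    cluster_lr: float = 1e-5
    target_update_interval: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be >= 2 for training")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.tae_lr < 0 or self.cluster_lr < 0:
            raise ValueError("learning rates must be nonnegative")
        if self.target_update_interval < 1:
            raise ValueError("target_update_interval must be >= 1")


@dataclass
class Centroids:
    values: np.ndarray  # (K, d)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("centroids must be a K x d matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite centroid")

    @property
    def K(self) -> int:
        return self.values.shape[0]


def _check_nonconstant(v: np.ndarray, what: str):
    if np.ptp(v) == 0:
        raise ValueError(f"{what} is constant: Pearson correlation undefined")


def pearson_similarity(z: np.ndarray, c: np.ndarray) -> float:
    """Pearson dissimilarity 2(1 - rho) between two latent vectors, in [0, 4]."""
    z = np.asarray(z, dtype=np.float64).ravel()
    c = np.asarray(c, dtype=np.float64).ravel()
    if z.size != c.size or z.size < 2:
        raise ValueError("vectors must share a length >= 2")
    _check_nonconstant(z, "z")
    _check_nonconstant(c, "c")
    zc, cc = z - z.mean(), c - c.mean()
    rho = (zc @ cc) / np.sqrt((zc @ zc) * (cc @ cc))
    return float(2.0 * (1.0 - rho))


def _similarity_matrix(Z: np.ndarray, C: np.ndarray) -> np.ndarray:
    """2(1 - rho) for every (instance, centroid) pair; validates variances."""
    Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
    C = np.atleast_2d(np.asarray(C, dtype=np.float64))
    if Z.shape[1] != C.shape[1]:
        raise ValueError("latent dimension mismatch")
    for i in range(Z.shape[0]):
        if np.ptp(Z[i]) == 0:
            raise ValueError(f"instance {i}: constant latent vector")
    for j in range(C.shape[0]):
        if np.ptp(C[j]) == 0:
            raise ValueError(f"centroid {j}: constant vector")
    zc = Z - Z.mean(axis=1, keepdims=True)
    cc = C - C.mean(axis=1, keepdims=True)
    num = zc @ cc.T
    den = np.sqrt((zc**2).sum(axis=1))[:, None] * np.sqrt((cc**2).sum(axis=1))[None, :]
    return 2.0 * (1.0 - num / den)


def soft_assign(Z: np.ndarray, C: np.ndarray | Centroids) -> np.ndarray:
    """Row-stochastic soft assignment Q from Student's-t weighting of the
    Pearson dissimilarity."""
    C = C.values if isinstance(C, Centroids) else C
    w = 1.0 / (1.0 + _similarity_matrix(Z, C))
    return w / w.sum(axis=1, keepdims=True)


def target_distribution(Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sharpened target distribution P and the cluster frequencies f."""
    Q = np.atleast_2d(np.asarray(Q, dtype=np.float64))
    if not np.allclose(Q.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("Q must be row-stochastic")
    f = Q.sum(axis=0)
    if np.any(f == 0):
        raise ValueError(f"dead cluster(s): {np.where(f == 0)[0].tolist()}")
    w = Q**2 / f
    return w / w.sum(axis=1, keepdims=True), f


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """sum_ij p_ij log(p_ij / q_ij), with 0 log 0 := 0."""
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    if P.shape != Q.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {Q.shape}")
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))


def init_centroids(latent: np.ndarray, K: int) -> tuple[Centroids, np.ndarray]:
    """Complete-linkage agglomerative clustering of the flattened latents;
    centroid j is the arithmetic mean of group j.  Returns the centroids
    and the initial hard labels."""
    latent = np.atleast_2d(np.asarray(latent, dtype=np.float64))
    n = latent.shape[0]
    if n < K:
        raise ValueError(f"need at least K={K} instances, got {n}")
    labels = AgglomerativeClustering(n_clusters=K, linkage="complete").fit_predict(
        latent
    )
    centroids = np.vstack([latent[labels == j].mean(axis=0) for j in range(K)])
    return Centroids(centroids), labels


# -- differentiable versions used inside the training loop ------------------


def _soft_assign_var(zflat: Var, c: Var) -> Var:
    zc = zflat - zflat.mean(axis=1, keepdims=True)
    cc = c - c.mean(axis=1, keepdims=True)
    num = zc @ cc.T
    sz = (zc**2).sum(axis=1, keepdims=True).sqrt()
    sc = (cc**2).sum(axis=1, keepdims=True).sqrt()
    rho = num / (sz @ sc.T)
    sim = (1.0 - rho) * 2.0
    w = (sim + 1.0) ** -1.0
    return w / w.sum(axis=1, keepdims=True)


def _kl_var(P: np.ndarray, Q: Var) -> Var:
    mask = P > 0
    const = float(np.sum(P[mask] * np.log(P[mask])))
    return Var(const) - (Var(P) * Q.log()).sum()


@dataclass
class TrainResult:
    labels: np.ndarray
    Q: np.ndarray
    centroids: Centroids
    history: list[tuple[float, float, float]]  # (J_total, J_MSE, J_KL)
    model: TAE
    init_labels: np.ndarray | None = None


def train(
    tensor: GaitTensor | np.ndarray,
    model: TAE,
    config: DTCConfig,
    epoch_callback=None,
) -> TrainResult:
    """Jointly optimize the autoencoder and the cluster centroids.

    Full-batch gradient descent on J_total = J_MSE + J_KL; the target
    distribution P is refreshed from the current full-data Q every
    ``target_update_interval`` epochs and treated as constant in between.
    Labels are the argmax of the final Q (ties to the lowest index).
    """
    rows = tensor.matrix if isinstance(tensor, GaitTensor) else np.asarray(tensor)
    n = rows.shape[0]
    if n < config.K:
        raise ValueError("fewer instances than clusters")

    latent0 = model.latent_matrix(rows)
    centroids0, init_labels = init_centroids(latent0, config.K)
    c_var = Var(centroids0.values.copy(), requires_grad=True)
    params = list(model.params.values())

    P: np.ndarray | None = None
    history: list[tuple[float, float, float]] = []
    x_var = Var(rows)
    for epoch in range(config.epochs):
        for p in params:
            p.zero_grad()
        c_var.zero_grad()

        z = model.encode(rows)
        zflat = z.reshape(n, model.latent_dim)
        q_var = _soft_assign_var(zflat, c_var)
        if epoch % config.target_update_interval == 0:
            P, f = target_distribution(q_var.data)
            if np.any(f < 1e-12):
                _reseed_dead(c_var, zflat.data, q_var.data, f)
                q_var = _soft_assign_var(zflat, c_var)
                P, f = target_distribution(q_var.data)
        xhat = model.decode(z)
        j_mse = _mse_var(x_var, xhat)
        j_kl = _kl_var(P, q_var)
        total = j_mse + j_kl
        if not np.isfinite(total.data):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        total.backward()

        for p in params:
            if p.grad is not None:
                p.data -= config.tae_lr * p.grad
        if c_var.grad is not None:
            c_var.data -= config.cluster_lr * c_var.grad
        history.append((float(total.data), float(j_mse.data), float(j_kl.data)))
        if epoch_callback is not None:
            epoch_callback(epoch, q_var.data, P)

    z_final = model.latent_matrix(rows)
    q_final = soft_assign(z_final, c_var.data)
    labels = np.argmax(q_final, axis=1)  # argmax ties resolve to lowest index
    return TrainResult(
        labels=labels,
        Q=q_final,
        centroids=Centroids(c_var.data.copy()),
        history=history,
        model=model,
        init_labels=init_labels,
    )


def _reseed_dead(c_var: Var, zflat: np.ndarray, Q: np.ndarray, f: np.ndarray):
    """Reseed centroids with (numerically) zero soft mass to the latent
    farthest from its assigned centroid."""
    for j in np.where(f < 1e-12)[0]:
        best = np.argmax(1.0 - Q.max(axis=1))
        c_var.data[j] = zflat[best]
        logger.warning("reseeded dead cluster %d to instance %d", j, best)


def run_dtc(
    tensor: GaitTensor | np.ndarray,
    K: int,
    tae_config: TAEConfig | None = None,
    dtc_config: DTCConfig | None = None,
) -> tuple[TrainResult, list[float]]:
    """Convenience wrapper: pretrain a fresh TAE, then jointly train at K."""
    from .temporal_autoencoder import pretrain

    tae_config = tae_config or TAEConfig()
    dtc_config = dtc_config or DTCConfig(K=K)
    if dtc_config.K != K:
        raise ValueError("K mismatch between argument and config")
    model, pre_history = pretrain(tensor, tae_config)
    result = train(tensor, model, dtc_config)
    return result, pre_history
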