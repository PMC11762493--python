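"""Cluster-count selection: silhouette sweep and singleton exclusion.

The cluster count is chosen by training the full model at each k in a
range (default 3..15), scoring the resulting partition with the silhouette
index on the flattened latent features, and then preferring the largest k
among the local silhouette peaks whose score stays within a tolerance of
the global maximum — fine-grained gait groups are more informative than a
marginally tighter coarse partition.  Clusters reduced to a single member
are treated as outliers: their instances are excluded, not reassigned, and
the remaining groups are relabeled consecutively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .gait_io import GaitTensor
from .temporal_autoencoder import TAE, TAEConfig, pretrain
from .temporal_clustering import DTCConfig, train

logger = logging.getLogger(__name__)

__all__ = [
    "silhouette_score",
    "sweep",
    "select_clusters",
    "exclude_small_clusters",
    "SweepRecord",
    "SweepResult",
    "FinalGrouping",
]


def silhouette_score(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette s(i) = (b(i) - a(i)) / max(a(i), b(i)) with Euclidean
    distances; members of singleton clusters score 0."""
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    labels = np.asarray(labels)
    n = points.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length != number of points")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = squareform(pdist(points))
    s = np.zeros(n)
    masks = {c: labels == c for c in uniq}
    for i in range(n):
        own = masks[labels[i]]
        if own.sum() == 1:
            s[i] = 0.0  # singleton convention
            continue
        a = D[i, own].sum() / (own.sum() - 1)
        b = min(D[i, masks[c]].mean() for c in uniq if c != labels[i])
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


@dataclass
class SweepRecord:
    k: int
    silhouette: float
    labels: np.ndarray | None
    cluster_sizes: np.ndarray | None
    n_singletons: int
    seed: int
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


@dataclass
class SweepResult:
    records: list[SweepRecord]
    latent_space: bool
    selected_k: int | None = None

    def record_for(self, k: int) -> SweepRecord:
        for r in self.records:
            if r.k == k:
                return r
        raise KeyError(k)


@dataclass
class FinalGrouping:
    selected_k: int
    labels: np.ndarray  # relabeled 0..G-1; excluded instances get -1
    n_groups: int
    group_sizes: np.ndarray
    excluded: np.ndarray  # indices of excluded instances
    silhouette: float


def sweep(
    tensor: GaitTensor | np.ndarray,
    k_range: range | tuple[int, int] = (3, 15),
    tae_config: TAEConfig | None = None,
    base_config: DTCConfig | None = None,
    latent_space: bool = True,
) -> SweepResult:
    """Train the full model at every k in `k_range` (inclusive bounds when a
    tuple) from one shared pretrained state, and silhouette-score each
    solution.

    Pretraining does not depend on k, so the TAE is pretrained once and each
    k restarts joint training from a copy of that state.  By default the
    silhouette is computed on the flattened latent features (the space the
    clustering operates in); ``latent_space=False`` scores in input space.
    """
    rows = tensor.matrix if isinstance(tensor, GaitTensor) else np.asarray(tensor)
    ks = list(k_range) if isinstance(k_range, range) else list(
        range(k_range[0], k_range[1] + 1)
    )
    if not ks:
        raise ValueError("empty k range")
    if min(ks) < 2 or max(ks) > rows.shape[0] - 1:
        raise ValueError(f"k range must lie within [2, N-1]={rows.shape[0] - 1}")
    tae_config = tae_config or TAEConfig()
    base_config = base_config or DTCConfig(K=ks[0])

    pretrained, _ = pretrain(rows, tae_config)
    state = pretrained.state_dict()

    records = []
    for k in ks:
        cfg = DTCConfig(
            K=k,
            epochs=base_config.epochs,
            tae_lr=base_config.tae_lr,
            cluster_lr=base_config.cluster_lr,
            target_update_interval=base_config.target_update_interval,
            seed=base_config.seed,
        )
        model = TAE(tae_config, rows.shape[1])
        model.load_state_dict(state)
        try:
            result = train(rows, model, cfg)
            space = model.latent_matrix(rows) if latent_space else rows
            ss = silhouette_score(space, result.labels)
            sizes = np.bincount(result.labels, minlength=k)
            records.append(
                SweepRecord(
                    k=k,
                    silhouette=ss,
                    labels=result.labels,
                    cluster_sizes=sizes,
                    n_singletons=int((sizes == 1).sum()),
                    seed=base_config.seed,
                )
            )
        except (ValueError, FloatingPointError) as exc:
            logger.warning("sweep failed at k=%d: %s", k, exc)
            records.append(
                SweepRecord(k=k, silhouette=float("nan"), labels=None,
                            cluster_sizes=None, n_singletons=0,
                            seed=base_config.seed, error=str(exc))
            )
    return SweepResult(records=records, latent_space=latent_space)


def exclude_small_clusters(
    labels: np.ndarray, min_cluster_size: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop clusters with fewer than `min_cluster_size` members.

    Returns (relabeled, group_sizes, excluded_indices): retained clusters
    are renumbered consecutively in order of their original label; excluded
    instances get label -1 and are listed, not reassigned.
    """
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    keep = uniq[counts >= min_cluster_size]
    if keep.size == 0:
        raise ValueError("all clusters fall below min_cluster_size")
    mapping = {old: new for new, old in enumerate(keep)}
    out = np.array([mapping.get(l, -1) for l in labels])
    excluded = np.where(out == -1)[0]
    sizes = np.bincount(out[out >= 0], minlength=keep.size)
    return out, sizes, excluded


def select_clusters(
    sweep_result: SweepResult,
    min_cluster_size: int = 2,
    tolerance: float = 0.9,
) -> FinalGrouping:
    """Pick the final solution from a sweep and drop outlier clusters.

    Among k whose silhouette is a local peak over the swept range, the
    largest k with score >= `tolerance` x the global maximum wins; its
    sub-`min_cluster_size` clusters are excluded and the rest relabeled.
    """
    ok = [r for r in sweep_result.records if not r.failed]
    if not ok:
        raise ValueError("sweep produced no successful records")
    ok.sort(key=lambda r: r.k)
    ss = np.array([r.silhouette for r in ok])
    if len(ok) == 1:
        chosen = ok[0]
    else:
        peaks = [
            i
            for i in range(len(ok))
            if (i == 0 or ss[i] >= ss[i - 1])
            and (i == len(ok) - 1 or ss[i] >= ss[i + 1])
        ]
        cutoff = tolerance * ss.max()
        candidates = [i for i in peaks if ss[i] >= cutoff]
        chosen = ok[max(candidates, key=lambda i: ok[i].k)]
    labels, sizes, excluded = exclude_small_clusters(chosen.labels, min_cluster_size)
    sweep_result.selected_k = chosen.k
    return FinalGrouping(
        selected_k=chosen.k,
        labels=labels,
        n_groups=sizes.size,
        group_sizes=sizes,
        excluded=excluded,
        silhouette=chosen.silhouette,
    )
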