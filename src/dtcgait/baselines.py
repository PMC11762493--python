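"""Time-series clustering baselines for the benchmark harness.

Each baseline consumes the same N x F feature matrix as the deep model,
treating every row as one univariate series, and is scored with this
package's silhouette implementation in input space (the baselines have no
latent space).  Implemented here:

- k-means with Euclidean distance (delegated to scikit-learn),
- k-means with dynamic time warping (DTW) distance and DTW barycenter
  averaging (DBA) centroid updates,
- k-means with soft-DTW distance; centroids update by the soft-alignment
  fixed point of the soft-DTW barycenter objective,
- k-Shape: shape-based distance (maximal normalized cross-correlation)
  with spectral shape extraction.

Dynamic programs are numba-compiled; everything is seeded.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .gait_io import GaitTensor
from .model_selection import silhouette_score

METHODS = ("kmeans-euclidean", "kmeans-dtw", "kmeans-softdtw", "kshape")


# -- dynamic time warping ---------------------------------------------------


@njit(cache=True)
def _dtw_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n, m = a.size, b.size
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(n):
        for j in range(m):
            cost = (a[i] - b[j]) ** 2
            D[i + 1, j + 1] = cost + min(
                D[i, j + 1], D[i + 1, j], D[i, j]
            )
    return D


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """DTW distance with squared ground cost, reported as a root (so it
    coincides with the Euclidean distance on the identity alignment)."""
    return float(np.sqrt(_dtw_matrix(np.asarray(a, float), np.asarray(b, float))[-1, -1]))


@njit(cache=True)
def _dtw_path(D: np.ndarray):
    i, j = D.shape[0] - 1, D.shape[1] - 1
    path = np.empty((i + j + 1, 2), dtype=np.int64)
    k = 0
    while i > 0 or j > 0:
        path[k, 0] = i - 1
        path[k, 1] = j - 1
        k += 1
        if i == 1 and j == 1:
            i, j = 0, 0
        elif i == 1:
            j -= 1
        elif j == 1:
            i -= 1
        else:
            diag, up, left = D[i - 1, j - 1], D[i - 1, j], D[i, j - 1]
            if diag <= up and diag <= left:
                i -= 1
                j -= 1
            elif up <= left:
                i -= 1
            else:
                j -= 1
    return path[:k]


def _dba_update(center: np.ndarray, members: np.ndarray, iters: int = 3) -> np.ndarray:
    """DTW barycenter averaging: align members to the center and average
    the values mapped onto each center index."""
    center = center.copy()
    for _ in range(iters):
        acc = np.zeros_like(center)
        cnt = np.zeros(center.size)
        for y in members:
            D = _dtw_matrix(center, y)
            for ci, yj in _dtw_path(D):
                acc[ci] += y[yj]
                cnt[ci] += 1.0
        center = acc / np.maximum(cnt, 1.0)
    return center


# -- soft-DTW ---------------------------------------------------------------


@njit(cache=True)
def _softdtw_R(a: np.ndarray, b: np.ndarray, gamma: float) -> np.ndarray:
    n, m = a.size, b.size
    R = np.full((n + 2, m + 2), np.inf)
    R[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = (a[i - 1] - b[j - 1]) ** 2
            r0 = -R[i - 1, j - 1] / gamma
            r1 = -R[i - 1, j] / gamma
            r2 = -R[i, j - 1] / gamma
            rmax = max(r0, max(r1, r2))
            rsum = (
                np.exp(r0 - rmax) + np.exp(r1 - rmax) + np.exp(r2 - rmax)
            )
            R[i, j] = cost + gamma * (-(np.log(rsum) + rmax))
    return R


@njit(cache=True)
def _softdtw_E(a: np.ndarray, b: np.ndarray, gamma: float, R: np.ndarray) -> np.ndarray:
    """Expected-alignment matrix E (gradient of the soft-DTW value with
    respect to the pairwise cost matrix)."""
    n, m = a.size, b.size
    E = np.zeros((n + 2, m + 2))
    E[n + 1, m + 1] = 1.0
    for j in range(m, 0, -1):
        R[n + 1, j] = -np.inf
    for i in range(n, 0, -1):
        R[i, m + 1] = -np.inf
    R[n + 1, m + 1] = R[n, m]
    for j in range(m, 0, -1):
        for i in range(n, 0, -1):
            c_right = (a[i - 1] - b[j]) ** 2 if j < m else 0.0
            c_down = (a[i] - b[j - 1]) ** 2 if i < n else 0.0
            c_diag = (a[i] - b[j]) ** 2 if (i < n and j < m) else 0.0
            ea = E[i + 1, j] * np.exp((R[i + 1, j] - R[i, j] - c_down) / gamma)
            eb = E[i, j + 1] * np.exp((R[i, j + 1] - R[i, j] - c_right) / gamma)
            ec = E[i + 1, j + 1] * np.exp(
                (R[i + 1, j + 1] - R[i, j] - c_diag) / gamma
            )
            E[i, j] = ea + eb + ec
    return E[1 : n + 1, 1 : m + 1]


def softdtw_distance(a: np.ndarray, b: np.ndarray, gamma: float = 1.0) -> float:
    """Soft-DTW value (squared ground cost, smoothing gamma); can be < 0."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(_softdtw_R(a, b, gamma)[a.size, b.size])


def _soft_barycenter(center: np.ndarray, members: np.ndarray,
                     gamma: float, iters: int = 3) -> np.ndarray:
    """Fixed-point iteration of the soft-DTW barycenter: each center sample
    becomes the alignment-weighted average of the samples it soft-aligns to."""
    center = center.copy()
    for _ in range(iters):
        num = np.zeros_like(center)
        den = np.zeros(center.size)
        for y in members:
            R = _softdtw_R(center, y, gamma)
            E = _softdtw_E(center, y, gamma, R.copy())
            num += E @ y
            den += E.sum(axis=1)
        center = num / np.maximum(den, 1e-12)
    return center


# -- k-Shape ----------------------------------------------------------------


def _znorm(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _ncc_max(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Max normalized cross-correlation over all shifts, and the shift."""
    n = x.size
    size = 1 << int(np.ceil(np.log2(2 * n - 1)))
    cc = np.fft.irfft(np.fft.rfft(x, size) * np.conj(np.fft.rfft(y, size)), size)
    cc = np.concatenate((cc[-(n - 1):], cc[:n]))
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom == 0:
        return 0.0, 0
    idx = int(np.argmax(cc))
    return float(cc[idx] / denom), idx - (n - 1)


def sbd_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Shape-based distance 1 - max NCC of the z-normalized series."""
    ncc, _ = _ncc_max(_znorm(np.asarray(x, float)), _znorm(np.asarray(y, float)))
    return float(1.0 - ncc)


def _shift(y: np.ndarray, s: int) -> np.ndarray:
    out = np.zeros_like(y)
    if s >= 0:
        out[s:] = y[: y.size - s]
    else:
        out[:s] = y[-s:]
    return out


def _shape_extraction(members: np.ndarray, center: np.ndarray) -> np.ndarray:
    aligned = []
    for y in members:
        yz = _znorm(y)
        if center.any():
            # center[t + s] ~ yz[t] at the best shift; move yz onto the center
            _, s = _ncc_max(center, yz)
            yz = _shift(yz, s)
        aligned.append(yz)
    Y = np.vstack(aligned)
    m, n = Y.shape
    S = Y.T @ Y
    Qm = np.eye(n) - np.ones((n, n)) / n
    M = Qm @ S @ Qm
    _, vec = eigh(M, subset_by_index=[n - 1, n - 1])
    c = vec[:, 0]
    # sign: correlate positively with the member average
    if np.dot(c, Y.mean(axis=0)) < 0:
        c = -c
    return _znorm(c)


# -- generic Lloyd iteration ------------------------------------------------


def _lloyd(
    rows: np.ndarray,
    k: int,
    seed: int,
    distance,
    update,
    max_iter: int,
    znorm_input: bool = False,
) -> np.ndarray:
    data = np.vstack([_znorm(r) for r in rows]) if znorm_input else rows
    rng = np.random.default_rng(seed)
    centers = data[rng.choice(len(data), size=k, replace=False)].copy()
    labels = np.full(len(data), -1)
    for _ in range(max_iter):
        D = np.array([[distance(x, c) for c in centers] for x in data])
        new_labels = D.argmin(axis=1)
        # keep clusters alive: move empty centers onto the worst-fit point
        for j in range(k):
            if not np.any(new_labels == j):
                far = int(np.argmax(D.min(axis=1)))
                centers[j] = data[far]
                new_labels[far] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            centers[j] = update(centers[j], data[labels == j])
    return labels


def kmeans_dtw(rows: np.ndarray, k: int, seed: int = 0, max_iter: int = 8) -> np.ndarray:
    return _lloyd(rows, k, seed, dtw_distance,
                  lambda c, mem: _dba_update(c, mem), max_iter)


def kmeans_softdtw(rows: np.ndarray, k: int, seed: int = 0, max_iter: int = 8,
                   gamma: float = 1.0) -> np.ndarray:
    return _lloyd(rows, k, seed,
                  lambda a, b: softdtw_distance(a, b, gamma),
                  lambda c, mem: _soft_barycenter(c, mem, gamma), max_iter)


def kshape(rows: np.ndarray, k: int, seed: int = 0, max_iter: int = 8) -> np.ndarray:
    return _lloyd(rows, k, seed, sbd_distance,
                  lambda c, mem: _shape_extraction(mem, c), max_iter,
                  znorm_input=True)


def kmeans_euclidean(rows: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    return KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(rows)


# -- benchmark report -------------------------------------------------------


@dataclass
class BenchmarkReport:
    scores: pd.DataFrame  # index: method, columns: k
    runtimes: pd.DataFrame
    seed: int
    failures: dict[tuple[str, int], str] = field(default_factory=dict)


def run_baselines(
    tensor: GaitTensor | np.ndarray,
    k_range: tuple[int, int] | range = (3, 15),
    seed: int = 0,
    methods: tuple[str, ...] = METHODS,
    max_iter: int = 8,
    dtc_scores: dict[int, float] | None = None,
) -> BenchmarkReport:
    """Silhouette of every baseline at every k on the shared feature matrix.

    Baseline silhouettes are computed in input space.  If `dtc_scores`
    (k -> silhouette from the deep model's sweep, computed in its latent
    space) is given, a ``dtcgait`` row is appended; the spatial asymmetry is
    inherent — the baselines have no latent space.
    Failures are recorded per cell, never fatal.
    """
    rows = tensor.matrix if isinstance(tensor, GaitTensor) else np.asarray(tensor)
    ks = list(k_range) if isinstance(k_range, range) else list(
        range(k_range[0], k_range[1] + 1)
    )
    runners = {
        "kmeans-euclidean": lambda k: kmeans_euclidean(rows, k, seed),
        "kmeans-dtw": lambda k: kmeans_dtw(rows, k, seed, max_iter),
        "kmeans-softdtw": lambda k: kmeans_softdtw(rows, k, seed, max_iter),
        "kshape": lambda k: kshape(rows, k, seed, max_iter),
    }
    scores = pd.DataFrame(index=list(methods), columns=ks, dtype=float)
    times = pd.DataFrame(index=list(methods), columns=ks, dtype=float)
    failures: dict[tuple[str, int], str] = {}
    for method in methods:
        for k in ks:
            t0 = time.perf_counter()
            try:
                labels = runners[method](k)
                scores.loc[method, k] = silhouette_score(rows, labels)
            except Exception as exc:  # record, continue
                failures[(method, k)] = str(exc)
                scores.loc[method, k] = np.nan
            times.loc[method, k] = time.perf_counter() - t0
    if dtc_scores is not None:
        scores.loc["dtcgait"] = [dtc_scores.get(k, np.nan) for k in ks]
        times.loc["dtcgait"] = np.nan
    return BenchmarkReport(scores=scores, runtimes=times, seed=seed,
                           failures=failures)
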