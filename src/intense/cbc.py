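"""Centroid-based clustering (k-means) of factors, with inertia-elbow
selection of the cluster count.

Factors are first embedded by PCA of the factor-profile space (each factor's
length-N standardized column is one observation), both for numerical
conditioning and because the 2-D embedding is the standard way to visualize
the result. K-means is then run on the embedded coordinates with many
restarts; the number of clusters is chosen as the elbow of the inertia
(within-cluster sum of squares) curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .clustering import FactorClustering, clustering_from_labels
from .cohort_io import NormalizedMatrix
from .exceptions import ConfigError, DegenerateDataError

DEFAULT_RESTARTS = 50


@dataclass
class FactorEmbedding:
    """F x D factor coordinates in the leading principal directions of the
    factor-profile space; axes ordered by decreasing variance."""

    coords: np.ndarray
    factor_names: list[str]

    @property
    def n_factors(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


def embed_factors(matrix: NormalizedMatrix, d: int = 2) -> FactorEmbedding:
    """PCA of the transposed (factor-as-observation) matrix, keeping the
    first ``d`` principal directions.

    With ``d = min(F, N)`` the embedding is an isometry of the factor
    profiles (pairwise Euclidean distances are preserved). Components use the
    same deterministic orientation as the subject-space PCA: the
    largest-|weight| entry of each direction is positive.
    """
    Y = matrix.values.T  # F x N factor profiles
    f, n = Y.shape
    if d < 1:
        raise ConfigError(f"embedding dimension must be >= 1, got {d}")
    if d > min(f, n):
        raise ConfigError(f"embedding dimension {d} exceeds min(F, N) = {min(f, n)}")
    Yc = Y - Y.mean(axis=0, keepdims=True)
    u, s, _vt = np.linalg.svd(Yc, full_matrices=False)
    coords = u[:, :d] * s[:d]
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return FactorEmbedding(coords=coords, factor_names=list(matrix.factor_names))


@dataclass
class KMeansResult:
    """Best-of-restarts k-means partition of the embedded factors."""

    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    k: int
    seed: int
    restarts: int
    factor_names: list[str]

    def to_clustering(self) -> FactorClustering:
        return clustering_from_labels(
            "CBC",
            self.factor_names,
            self.labels,
            {"k": self.k, "seed": self.seed, "restarts": self.restarts},
        )


def kmeans_factors(
    emb: FactorEmbedding, k: int, seed: int = 0, restarts: int = DEFAULT_RESTARTS
) -> KMeansResult:
    """Lloyd k-means with k-means++ initialization and ``restarts``
    independent starts; deterministic given ``seed``."""
    if not 1 <= k <= emb.n_factors:
        raise ConfigError(f"k must be in [1, {emb.n_factors}], got {k}")
    distinct = np.unique(emb.coords, axis=0).shape[0]
    if k > distinct:
        raise DegenerateDataError(
            f"k = {k} exceeds the number of distinct factor points ({distinct})"
        )
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(emb.coords)
    # recompute inertia exactly as assigned (authoritative value)
    inertia = float(((emb.coords - km.cluster_centers_[labels]) ** 2).sum())
    return KMeansResult(
        labels=labels,
        centroids=km.cluster_centers_,
        inertia=inertia,
        k=k,
        seed=seed,
        restarts=restarts,
        factor_names=list(emb.factor_names),
    )


@dataclass
class KSelection:
    """Elbow-selected cluster count plus the full inertia curve for audit."""

    k: int
    inertia_curve: dict[int, float]
    flat: bool = False


# elbow curvature half-window; 3 steps damps restart noise and single-step
# raggedness of the inertia curve
ELBOW_WINDOW = 3

_LOG_FLOOR = 1e-12  # inertia clip so exact-duplicate factor points stay finite


def _elbow(curve: dict[int, float], k_min: int, k_max: int) -> tuple[int | None, float]:
    """Argmax of the symmetric second difference of log-inertia.

    The log scale makes the bend criterion scale-invariant: on k-means
    inertia curves the early absolute drops dominate any raw-scale second
    difference, whereas the elbow is where the *relative* decay rate
    collapses. At each candidate k the half-window is
    ``w = min(ELBOW_WINDOW, k - lo, hi - k)`` and the curvature score is
    ``(log c[k-w] - 2 log c[k] + log c[k+w]) / w^2``, so short curves and
    candidates near the ends use the widest symmetric window available.
    """
    lo, hi = min(curve), max(curve)
    logc = {k: np.log(max(v, _LOG_FLOOR)) for k, v in curve.items()}
    best_k, best_score = None, 0.0
    for k in range(k_min, k_max + 1):
        w = min(ELBOW_WINDOW, k - lo, hi - k)
        if w < 1:
            continue
        score = (logc[k - w] - 2 * logc[k] + logc[k + w]) / w**2
        if best_k is None or score > best_score:
            best_k, best_score = k, score
    return best_k, best_score


def select_k(
    emb: FactorEmbedding,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    restarts: int = DEFAULT_RESTARTS,
) -> KSelection:
    """Pick the number of clusters as the elbow of the inertia curve.

    The inertia curve is evaluated on ``[k_min - w, k_max + w]`` (clipped to
    [1, F - 1]) and the elbow is the k in ``k_range`` with the largest
    log-scale curvature (see :func:`_elbow`). A flat curve — no candidate
    with positive curvature — returns the smallest k with a warning.
    """
    k_min, k_max = k_range
    if not 2 <= k_min <= k_max <= emb.n_factors - 1:
        raise ConfigError(f"k_range must satisfy 2 <= k_min <= k_max <= F-1, got {k_range}")
    lo = max(1, k_min - ELBOW_WINDOW)
    hi = min(emb.n_factors - 1, k_max + ELBOW_WINDOW)
    curve = {
        k: kmeans_factors(emb, k, seed=seed, restarts=restarts).inertia
        for k in range(lo, hi + 1)
    }
    best_k, best_score = _elbow(curve, k_min, k_max)
    if best_k is None or best_score <= 0:
        warnings.warn("inertia curve has no elbow (no positive curvature); returning k_min")
        return KSelection(k=k_min, inertia_curve=curve, flat=True)
    return KSelection(k=best_k, inertia_curve=curve)
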