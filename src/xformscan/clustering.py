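"""Clustering sweeps on embedded coordinates.

K-Means sweeps k from ceil(L/2) to L+4 (L = number of reference labels),
with 20 random restarts of at most 50 iterations per k. DBSCAN sweeps
eps over 0.5, 1.0, ..., 10.0 with min_samples fixed at 8. Both return
the partition that maximizes a pluggable score function — ARI against
provided labels in supervised mode, silhouette when no labels exist.
Louvain community detection on a kNN graph is available as the
graph-based alternative (the "PCA30 + Louvain" style protocol).
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.cluster import DBSCAN, KMeans
from sklearn.neighbors import NearestNeighbors

from .embedding import Embedding
from .metrics import adjusted_rand_index, silhouette

__all__ = [
    "ClusteringResult",
    "kmeans_sweep",
    "dbscan_sweep",
    "louvain_cluster",
    "ari_scorer",
    "silhouette_scorer",
]

# score functions take (coords, labels) and return a float (higher = better)
ScoreFn = Callable[[np.ndarray, np.ndarray], float]


@dataclass
class ClusteringResult:
    labels: np.ndarray  # per-cell int, -1 = noise
    algorithm: str
    params: dict
    score: float
    sweep: list[tuple[dict, float]] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and np.all(self.labels == -1):
            raise ValueError("clustering produced only noise")


def ari_scorer(true_labels) -> ScoreFn:
    """Supervised sweep score: ARI against reference labels."""
    truth = np.asarray(true_labels)

    def score(coords: np.ndarray, labels: np.ndarray) -> float:
        return adjusted_rand_index(truth, labels)

    return score


def silhouette_scorer() -> ScoreFn:
    """Unsupervised sweep score: euclidean silhouette (−inf if undefined)."""

    def score(coords: np.ndarray, labels: np.ndarray) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = silhouette(coords, labels)
        return -math.inf if s is None else s

    return score


def _coords(emb) -> np.ndarray:
    return emb.coords if isinstance(emb, Embedding) else np.asarray(emb, dtype=float)


def kmeans_range(n_reference_labels: int) -> list[int]:
    """The swept k values: ceil(L/2) .. L+4 inclusive."""
    if n_reference_labels < 2:
        raise ValueError("need at least 2 reference labels")
    lo = math.ceil(n_reference_labels / 2)
    return list(range(lo, n_reference_labels + 5))


def kmeans_sweep(emb, n_reference_labels: int, score_fn: ScoreFn, seed: int = 0) -> ClusteringResult:
    """K-Means over the k sweep; returns the best-scoring partition.

    Each k runs 20 random restarts capped at 50 iterations.
    """
    coords = _coords(emb)
    ks = kmeans_range(n_reference_labels)
    if coords.shape[0] < ks[0]:
        raise ValueError(f"{coords.shape[0]} cells is fewer than smallest k={ks[0]}")
    best = None
    sweep: list[tuple[dict, float]] = []
    for k in ks:
        if k > coords.shape[0]:
            continue
        km = KMeans(n_clusters=k, n_init=20, max_iter=50, random_state=seed)
        labels = km.fit_predict(coords)
        s = score_fn(coords, labels)
        sweep.append(({"k": k}, s))
        if best is None or s > best[1]:
            best = (labels, s, {"k": k})
    labels, s, params = best
    return ClusteringResult(labels=labels, algorithm="kmeans", params=params, score=s, sweep=sweep)


DBSCAN_EPS_GRID = tuple(np.arange(1, 21) * 0.5)  # 0.5, 1.0, ..., 10.0
DBSCAN_MIN_SAMPLES = 8


def dbscan_sweep(emb, score_fn: ScoreFn) -> ClusteringResult:
    """DBSCAN over the 20-value eps grid with min_samples = 8.

    eps values whose partitions are all noise are recorded with score
    −inf; if every eps is all-noise the sweep fails.
    """
    coords = _coords(emb)
    if coords.shape[0] < DBSCAN_MIN_SAMPLES:
        raise ValueError(f"DBSCAN needs at least {DBSCAN_MIN_SAMPLES} cells")
    best = None
    sweep: list[tuple[dict, float]] = []
    for eps in DBSCAN_EPS_GRID:
        labels = DBSCAN(eps=eps, min_samples=DBSCAN_MIN_SAMPLES).fit_predict(coords)
        if np.all(labels == -1):
            sweep.append(({"eps": float(eps)}, -math.inf))
            continue
        s = score_fn(coords, labels)
        sweep.append(({"eps": float(eps)}, s))
        if best is None or s > best[1]:
            best = (labels, s, {"eps": float(eps), "min_samples": DBSCAN_MIN_SAMPLES})
    if best is None:
        raise ValueError("no clusters found: every eps yielded all-noise")
    labels, s, params = best
    return ClusteringResult(labels=labels, algorithm="dbscan", params=params, score=s, sweep=sweep)


def louvain_cluster(emb, n_neighbors: int = 15, seed: int = 0, resolution: float = 1.0) -> ClusteringResult:
    """Louvain modularity communities on a kNN graph of the embedding."""
    import igraph as ig

    coords = _coords(emb)
    n = coords.shape[0]
    if n_neighbors >= n:
        raise ValueError("n_neighbors must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    graph = ig.Graph(n=n, edges=sorted(edges))
    ig.set_random_number_generator(random.Random(seed))
    try:
        communities = graph.community_multilevel(resolution=resolution)
    finally:
        ig.set_random_number_generator(random)
    labels = np.asarray(communities.membership, dtype=int)
    return ClusteringResult(
        labels=labels,
        algorithm="louvain",
        params={"n_neighbors": n_neighbors, "resolution": resolution, "seed": seed},
        score=float(communities.modularity),
        sweep=[],
    )


def cluster(emb, algorithm: str, score_fn: ScoreFn, n_reference_labels: int | None = None, seed: int = 0) -> ClusteringResult:
    """Dispatch by name: 'kmeans', 'dbscan' or 'louvain'."""
    algorithm = algorithm.lower()
    if algorithm == "kmeans":
        if n_reference_labels is None:
            raise ValueError("kmeans sweep needs the number of reference labels")
        return kmeans_sweep(emb, n_reference_labels, score_fn, seed=seed)
    if algorithm == "dbscan":
        return dbscan_sweep(emb, score_fn)
    if algorithm == "louvain":
        return louvain_cluster(emb, seed=seed)
    raise ValueError(f"unknown clustering algorithm {algorithm!r}")
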