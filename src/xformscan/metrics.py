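"""Partition-quality and batch-mixing metrics.

The adjusted Rand index (ARI) is the core statistic: it is computed here
from the contingency table,

    ARI = (sum_ij C(n_ij,2) - E) / (max - E)
    E   = sum_i C(a_i,2) * sum_j C(b_j,2) / C(n,2)
    max = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2

where n_ij are contingency counts and a_i, b_j the marginals. The
batch-wise ARI (bARI) is the same statistic between cluster labels and
batch identifiers; a value near 0 means batches are well mixed across
clusters, and it is reported alongside its 1-bARI transform. NMI and
silhouette delegate to scikit-learn.

DBSCAN noise points (label -1) count as one extra cluster for ARI/bARI
but are excluded from the cluster count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import comb
from sklearn.metrics import normalized_mutual_info_score, silhouette_score

__all__ = [
    "MetricsRecord",
    "adjusted_rand_index",
    "batch_metrics",
    "nmi",
    "silhouette",
    "count_clusters",
    "compute_metrics",
]


@dataclass
class MetricsRecord:
    """All evaluation statistics for one pipeline configuration."""

    ari: float | None
    bari: float | None
    one_minus_bari: float | None
    nmi: float | None
    silhouette: float | None
    n_clusters: int

    def as_dict(self) -> dict:
        return {
            "ari": self.ari,
            "bari": self.bari,
            "one_minus_bari": self.one_minus_bari,
            "nmi": self.nmi,
            "silhouette": self.silhouette,
            "n_clusters": self.n_clusters,
        }


def _check_pair(labels_a, labels_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"label vectors must be 1-D and equal length, got {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    return a, b


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions, in [-1, 1]."""
    a, b = _check_pair(labels_a, labels_b)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    n = a.size
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    sum_ij = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial (all-in-one or all-singletons)
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))


def batch_metrics(cluster_labels, batch_ids) -> tuple[float | None, float | None]:
    """bARI = ARI(batch ids, cluster labels) and its 1-bARI transform.

    Low |bARI| indicates well-mixed batches; 1-bARI can exceed 1 when
    bARI is negative. With a single batch the statistic is undefined and
    (None, None) is returned with a warning.
    """
    cluster_labels, batch_ids = _check_pair(cluster_labels, batch_ids)
    if len(np.unique(batch_ids)) < 2:
        warnings.warn("single batch present: bARI undefined", stacklevel=2)
        return None, None
    bari = adjusted_rand_index(batch_ids, cluster_labels)
    return bari, 1.0 - bari


def nmi(labels_a, labels_b) -> float:
    """Mutual information normalized by the arithmetic mean of entropies."""
    a, b = _check_pair(labels_a, labels_b)
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def silhouette(coords, labels) -> float | None:
    """Mean euclidean silhouette width; None when fewer than 2 clusters."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        warnings.warn("fewer than 2 clusters: silhouette undefined", stacklevel=2)
        return None
    return float(silhouette_score(np.asarray(coords, dtype=float), labels, metric="euclidean"))


def count_clusters(labels) -> int:
    """Number of distinct labels, excluding the noise label -1."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return 0
    uniq = np.unique(labels)
    return int(np.sum(uniq != -1))


def compute_metrics(
    coords,
    cluster_labels,
    batch_ids=None,
    true_labels=None,
) -> MetricsRecord:
    """Assemble a MetricsRecord for one clustering on one embedding."""
    cluster_labels = np.asarray(cluster_labels)
    ari_val = nmi_val = None
    if true_labels is not None:
        ari_val = adjusted_rand_index(true_labels, cluster_labels)
        nmi_val = nmi(true_labels, cluster_labels)
    bari = omb = None
    if batch_ids is not None:
        bari, omb = batch_metrics(cluster_labels, batch_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sil = silhouette(coords, cluster_labels)
    return MetricsRecord(
        ari=ari_val,
        bari=bari,
        one_minus_bari=omb,
        nmi=nmi_val,
        silhouette=sil,
        n_clusters=count_clusters(cluster_labels),
    )
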