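"""Low-dimensional embeddings: PCA, t-SNE and UMAP.

t-SNE and UMAP are always 2-dimensional here; t-SNE uses random (not
PCA) initialization and UMAP uses spectral initialization. PCA centers
but does not rescale — any rescaling is the transform chain's job. The
perplexity / neighbor-count defaults below are ordinary values for
single-cell work and are recorded in the run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .datamodel import ExpressionMatrix

__all__ = ["Embedding", "embed_pca", "embed_tsne", "embed_umap", "embed"]


@dataclass
class Embedding:
    coords: np.ndarray  # cells x d
    method: str
    d: int
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding produced non-finite coordinates")


def _as_matrix(X) -> np.ndarray:
    return X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)


def embed_pca(X, d: int = 2, seed: int = 0) -> Embedding:
    """Project onto the top-d principal axes of the mean-centered data."""
    V = _as_matrix(X)
    if d > min(V.shape):
        raise ValueError(f"d={d} exceeds min(n_cells, n_genes)={min(V.shape)}")
    pca = PCA(n_components=d, svd_solver="full")
    coords = pca.fit_transform(V)
    return Embedding(
        coords=coords,
        method="pca",
        d=d,
        seed=seed,
        params={"explained_variance_ratio": pca.explained_variance_ratio_.tolist()},
    )


def embed_tsne(X, seed: int = 0, perplexity: float = 30.0) -> Embedding:
    """2-D t-SNE with random initialization (no PCA warm start)."""
    V = _as_matrix(X)
    if V.shape[0] < 5:
        raise ValueError("t-SNE needs at least 5 cells")
    perp = min(perplexity, (V.shape[0] - 1) / 3.0)
    ts = TSNE(n_components=2, init="random", perplexity=perp, random_state=seed)
    coords = ts.fit_transform(V)
    return Embedding(coords=coords, method="tsne", d=2, seed=seed, params={"perplexity": perp})


def embed_umap(
    X, seed: int = 0, n_neighbors: int = 15, min_dist: float = 0.1
) -> Embedding:
    """2-D UMAP with spectral initialization and seeded determinism."""
    import umap  # deferred: numba compilation is slow at import time

    V = _as_matrix(X)
    if V.shape[0] < 5:
        raise ValueError("UMAP needs at least 5 cells")
    nn = min(n_neighbors, V.shape[0] - 1)
    reducer = umap.UMAP(
        n_components=2,
        init="spectral",
        n_neighbors=nn,
        min_dist=min_dist,
        random_state=seed,
    )
    coords = reducer.fit_transform(V)
    return Embedding(
        coords=coords,
        method="umap",
        d=2,
        seed=seed,
        params={"n_neighbors": nn, "min_dist": min_dist},
    )


def embed(X, method: str, seed: int = 0) -> Embedding:
    """Dispatch by name: 'pca2', 'pca30', 'pca', 'tsne' or 'umap'."""
    method = method.lower()
    if method.startswith("pca"):
        d = int(method[3:]) if len(method) > 3 else 2
        return embed_pca(X, d=d, seed=seed)
    if method == "tsne":
        return embed_tsne(X, seed=seed)
    if method == "umap":
        return embed_umap(X, seed=seed)
    raise ValueError(f"unknown embedding method {method!r}")
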