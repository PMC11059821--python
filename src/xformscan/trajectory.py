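"""Diffusion pseudotime and trajectory-conservation scoring.

Pseudotime is the diffusion distance from a root cell: a symmetric kNN
graph is built with a Gaussian kernel whose bandwidth adapts to the
local scale (the distance to the k-th neighbor), the kernel is
row-normalized into a Markov transition operator, and each cell is
mapped to the diffusion coordinates ``[lambda_i / (1 - lambda_i)] psi_i``
built from the operator's nontrivial eigenpairs. A cell's pseudotime is
its euclidean distance from the root in those coordinates, so the root
sits at 0 and distance accumulates along the data manifold rather than
through ambient space.

Trajectory conservation is the Spearman rank correlation between
pseudotime and externally assigned integer stage times.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import spearmanr
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "stage_to_time",
    "diffusion_pseudotime",
    "trajectory_conservation",
    "medoid_root",
]


def stage_to_time(stages, stage_order: list[str]) -> np.ndarray:
    """Map per-cell stage labels to integer times (index in stage_order)."""
    lookup = {s: i for i, s in enumerate(stage_order)}
    out = np.empty(len(stages), dtype=int)
    for i, s in enumerate(stages):
        if s not in lookup:
            raise ValueError(f"unknown stage label {s!r}; known: {stage_order}")
        out[i] = lookup[s]
    return out


def _knn_kernel(coords: np.ndarray, n_neighbors: int) -> sp.csr_matrix:
    """Symmetric Gaussian kNN kernel with adaptive bandwidth."""
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    sigma = dist[:, -1]  # distance to k-th neighbor
    sigma = np.where(sigma > 0, sigma, 1e-12)
    rows = np.repeat(np.arange(n), n_neighbors)
    cols = idx[:, 1:].ravel()
    d = dist[:, 1:].ravel()
    w = np.exp(-(d**2) / (sigma[rows] * sigma[cols]))
    W = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    W = W.maximum(W.T)  # symmetrize: union of kNN edges
    return W


def diffusion_pseudotime(
    X,
    root,
    n_neighbors: int = 15,
    n_comps: int = 15,
    cell_ids: list[str] | None = None,
) -> np.ndarray:
    """Diffusion-distance pseudotime from a root cell.

    Parameters
    ----------
    X
        Coordinates (cells x features) of the representation on which to
        build the neighbor graph — typically an embedding or transformed
        expression matrix.
    root
        Row index of the root cell, or its id when ``cell_ids`` given.
    n_neighbors, n_comps
        Graph degree and number of nontrivial eigenpairs retained.

    If the neighbor graph is disconnected, pseudotime is computed on the
    root's component and cells outside it get NaN (with a warning).
    """
    coords = np.asarray(X, dtype=float)
    n = coords.shape[0]
    if isinstance(root, str):
        if cell_ids is None:
            raise ValueError("root given as id but cell_ids not provided")
        try:
            root = cell_ids.index(root)
        except ValueError:
            raise ValueError(f"root cell {root!r} not found") from None
    root = int(root)
    if not (0 <= root < n):
        raise ValueError(f"root index {root} out of range for {n} cells")
    if n < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} cells, got {n}")

    W = _knn_kernel(coords, n_neighbors)
    n_comp, comp = connected_components(W, directed=False)
    mask = np.ones(n, dtype=bool)
    if n_comp > 1:
        warnings.warn(
            f"neighbor graph has {n_comp} components; using the root's component",
            stacklevel=2,
        )
        mask = comp == comp[root]
        W = W[mask][:, mask]
    m = int(mask.sum())

    deg = np.asarray(W.sum(axis=1)).ravel()
    deg = np.where(deg > 0, deg, 1e-12)
    # symmetric conjugate of the row-normalized operator: same spectrum,
    # eigenvectors psi = D^{-1/2} v
    Dmh = sp.diags(1.0 / np.sqrt(deg))
    S = Dmh @ W @ Dmh
    k = min(n_comps + 1, m - 1)
    if k < 2:
        raise ValueError("degenerate neighbor graph: too few cells in root component")
    if m <= 200:
        evals, evecs = np.linalg.eigh(S.toarray())
        evals, evecs = evals[::-1][:k], evecs[:, ::-1][:, :k]
    else:
        evals, evecs = sp.linalg.eigsh(S, k=k, which="LA")
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
    psi = (evecs.T / np.sqrt(deg)).T
    # drop the trivial stationary eigenpair (lambda = 1)
    lam, psi = evals[1:], psi[:, 1:]
    lam = np.clip(lam, None, 1.0 - 1e-10)
    dmap = psi * (lam / (1.0 - lam))
    local_root = int(np.flatnonzero(mask).searchsorted(root)) if n_comp > 1 else root
    diff = dmap - dmap[local_root]
    dpt_local = np.linalg.norm(diff, axis=1)
    dpt = np.full(n, np.nan)
    dpt[mask] = dpt_local
    return dpt


def trajectory_conservation(pseudotime, true_time) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    pt = np.asarray(pseudotime, dtype=float)
    tt = np.asarray(true_time, dtype=float)
    if pt.shape != tt.shape or pt.size < 3:
        raise ValueError("need >= 3 paired observations")
    ok = np.isfinite(pt)
    if np.unique(tt[ok]).size < 2:
        raise ValueError("true_time is constant: correlation undefined")
    rho = spearmanr(pt[ok], tt[ok]).statistic
    return float(rho)


def medoid_root(coords, stages, stage_order: list[str]) -> int:
    """Root choice when none is given: the medoid of the earliest stage.

    Among cells labeled with the first stage in ``stage_order``, returns
    the index minimizing the summed euclidean distance to the others.
    """
    coords = np.asarray(coords, dtype=float)
    stages = np.asarray(stages)
    first = stage_order[0]
    cand = np.flatnonzero(stages == first)
    if cand.size == 0:
        raise ValueError(f"no cells carry the earliest stage {first!r}")
    sub = coords[cand]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1) ** 0.5
    return int(cand[np.argmin(d2.sum(axis=1))])
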