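"""Grid orchestration and the transformation-recommendation rule.

``run_grid`` evaluates every (transform chain) x (embedding) x
(clustering) combination on one dataset and collects a metrics row per
combination; a failure inside one cell is recorded on its row and never
aborts the sweep. ``recommend_transform`` then ranks chains by the
batch-mixing rule: keep rows whose batch-ARI magnitude is at most a
threshold (default 0.05; if none qualify, the lowest-|bARI| quartile),
rank the kept rows by closeness of their cluster count to the expected
number of cell types, and break ties by silhouette. The rationale
string spells out those three quantities for each ranked chain.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as xio
from .clustering import ari_scorer, cluster, silhouette_scorer
from .datamodel import ExpressionMatrix
from .embedding import embed
from .metrics import MetricsRecord, compute_metrics
from .transforms import TransformChain, apply_chain, enumerate_chains

__all__ = ["GridRow", "GridResult", "Recommendation", "run_grid", "recommend_transform", "run_report"]


@dataclass
class GridRow:
    chain_name: str
    embed_method: str
    cluster_algorithm: str
    params: dict
    metrics: MetricsRecord | None
    error: str | None = None
    seconds: float = 0.0

    def as_dict(self) -> dict:
        # timing stays on the object (logged), not in the table: result
        # CSVs are byte-identical across same-seed re-runs
        base = {
            "chain": self.chain_name,
            "embed": self.embed_method,
            "cluster": self.cluster_algorithm,
            "params": json.dumps(self.params, sort_keys=True),
            "error": self.error or "",
        }
        m = (
            self.metrics.as_dict()
            if self.metrics is not None
            else {k: None for k in ("ari", "bari", "one_minus_bari", "nmi", "silhouette", "n_clusters")}
        )
        return {**base, **m}


@dataclass
class GridResult:
    rows: list[GridRow]
    manifest: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.rows])

    def ok_rows(self) -> list[GridRow]:
        return [r for r in self.rows if r.error is None and r.metrics is not None]


@dataclass
class Recommendation:
    ranked: list[dict]  # chain, bari, n_clusters, silhouette, rationale
    bari_threshold: float
    expected_n_types: int | None

    @property
    def best_chain(self) -> str:
        return self.ranked[0]["chain"]

    def rationale_text(self) -> str:
        lines = [
            "Transformation ranking by batch-mixing rule "
            f"(|bARI| <= {self.bari_threshold}, then cluster count vs expected "
            f"{self.expected_n_types}, then silhouette):"
        ]
        lines += [f"{i + 1}. {r['rationale']}" for i, r in enumerate(self.ranked)]
        return "\n".join(lines)


def run_grid(
    X: ExpressionMatrix,
    chains: list[TransformChain] | None = None,
    embedders: list[str] = ("pca2",),
    clusterers: list[str] = ("kmeans",),
    seed: int = 0,
    label_col: str = "cell_type",
    n_reference_labels: int | None = None,
) -> GridResult:
    """Evaluate every chain x embedder x clusterer combination.

    Sweeps are scored by ARI against ``label_col`` when present
    (supervised benchmarking) and by silhouette otherwise. The K-Means
    sweep range derives from the number of reference labels; without
    labels ``n_reference_labels`` (default 8) anchors it. Failures in a
    single combination are recorded on the row.
    """
    if chains is None:
        chains = enumerate_chains()
    if not chains:
        raise ValueError("empty chain list")
    labels = X.labels(label_col)
    labels_np = None if labels is None else labels.to_numpy()
    try:
        batches = X.batches.to_numpy()
    except KeyError:
        batches = None
    rows: list[GridRow] = []
    for chain in chains:
        if isinstance(chain, str):
            chain = TransformChain.from_name(chain)
        try:
            Xt = apply_chain(X, chain)
        except ValueError as exc:
            for em in embedders:
                for cl in clusterers:
                    rows.append(GridRow(chain.name, em, cl, {}, None, error=str(exc)))
            continue
        for em in embedders:
            try:
                t0 = time.perf_counter()
                embedding = embed(Xt, em, seed=seed)
            except Exception as exc:  # noqa: BLE001 - isolation contract
                for cl in clusterers:
                    rows.append(GridRow(chain.name, em, cl, {}, None, error=str(exc)))
                continue
            for cl in clusterers:
                t1 = time.perf_counter()
                try:
                    if labels_np is not None:
                        score_fn = ari_scorer(labels_np)
                        n_ref = len(np.unique(labels_np))
                    else:
                        score_fn = silhouette_scorer()
                        n_ref = n_reference_labels or 8
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = cluster(embedding, cl, score_fn, n_reference_labels=n_ref, seed=seed)
                        rec = compute_metrics(
                            embedding.coords, res.labels, batch_ids=batches, true_labels=labels_np
                        )
                    rows.append(
                        GridRow(
                            chain.name, em, cl, res.params, rec,
                            seconds=time.perf_counter() - t0 + (time.perf_counter() - t1),
                        )
                    )
                except Exception as exc:  # noqa: BLE001
                    rows.append(GridRow(chain.name, em, cl, {}, None, error=str(exc)))
    manifest = {
        "seed": seed,
        "chains": [c.name if isinstance(c, TransformChain) else str(c) for c in chains],
        "embedders": list(embedders),
        "clusterers": list(clusterers),
        "supervised": labels_np is not None,
        "n_cells": X.n_cells,
        "n_genes": X.n_genes,
    }
    return GridResult(rows=rows, manifest=manifest)


def recommend_transform(
    grid: GridResult,
    expected_n_types: int | None = None,
    bari_threshold: float = 0.05,
) -> Recommendation:
    """Rank transformation chains by batch mixing and cluster count.

    Keeps rows with |bARI| <= threshold (or, if none qualify, the
    lowest-|bARI| quartile); ranks by |n_clusters - expected_n_types|
    when an expected count is given; ties break toward higher
    silhouette. When one chain appears in several pipeline rows its
    best-ranked row represents it.
    """
    candidates = [r for r in grid.ok_rows() if r.metrics.bari is not None]
    if not candidates:
        raise ValueError("no rows with a defined batch-ARI (all errored or single batch)")
    kept = [r for r in candidates if abs(r.metrics.bari) <= bari_threshold]
    if not kept:
        ranked_by_bari = sorted(candidates, key=lambda r: abs(r.metrics.bari))
        kept = ranked_by_bari[: max(1, len(candidates) // 4)]

    def sort_key(r: GridRow):
        cluster_gap = (
            abs(r.metrics.n_clusters - expected_n_types) if expected_n_types is not None else 0
        )
        sil = r.metrics.silhouette if r.metrics.silhouette is not None else -np.inf
        return (cluster_gap, -sil, abs(r.metrics.bari), r.chain_name)

    ranked_rows = sorted(kept, key=sort_key)
    seen: set[str] = set()
    ranked: list[dict] = []
    for r in ranked_rows:
        if r.chain_name in seen:
            continue
        seen.add(r.chain_name)
        m = r.metrics
        ranked.append(
            {
                "chain": r.chain_name,
                "embed": r.embed_method,
                "cluster": r.cluster_algorithm,
                "bari": m.bari,
                "n_clusters": m.n_clusters,
                "silhouette": m.silhouette,
                "rationale": (
                    f"{r.chain_name}: bARI={m.bari:+.3f}, {m.n_clusters} clusters"
                    + (
                        f" (expected {expected_n_types})"
                        if expected_n_types is not None
                        else ""
                    )
                    + (
                        f", silhouette={m.silhouette:.3f}"
                        if m.silhouette is not None
                        else ", silhouette undefined"
                    )
                ),
            }
        )
    return Recommendation(ranked=ranked, bari_threshold=bari_threshold, expected_n_types=expected_n_types)


def run_report(
    grid: GridResult,
    recommendation: Recommendation | None,
    out_dir: str | Path,
    X: ExpressionMatrix | None = None,
    plots: bool = False,
) -> list[Path]:
    """Write results CSV, manifest JSON, recommendation text and plots."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    csv_path = out_dir / "results.csv"
    xio.write_results(grid, csv_path)
    written.append(csv_path)
    manifest_path = out_dir / "manifest.json"
    xio.write_manifest(grid.manifest, manifest_path)
    written.append(manifest_path)
    if recommendation is not None:
        rec_path = out_dir / "recommendation.txt"
        rec_path.write_text(recommendation.rationale_text() + "\n")
        written.append(rec_path)
    if plots and X is not None and recommendation is not None:
        written += _scatter_plots(X, recommendation, out_dir, seed=grid.manifest.get("seed", 0))
    return written


def _scatter_plots(X: ExpressionMatrix, rec: Recommendation, out_dir: Path, seed: int) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    best = rec.ranked[0]
    Xt = apply_chain(X, TransformChain.from_name(best["chain"]))
    emb = embed(Xt, best["embed"], seed=seed)
    written = []
    for color_col in ("batch", "cell_type"):
        if color_col not in X.meta.columns:
            continue
        fig, ax = plt.subplots(figsize=(5, 4))
        groups = X.meta[color_col].astype(str)
        for g in sorted(groups.unique()):
            m = (groups == g).to_numpy()
            ax.scatter(emb.coords[m, 0], emb.coords[m, 1], s=6, label=g, alpha=0.7)
        ax.set_title(f"{best['chain']} / {best['embed']} by {color_col}")
        ax.legend(fontsize=6, markerscale=2)
        path = out_dir / f"scatter_{color_col}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
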