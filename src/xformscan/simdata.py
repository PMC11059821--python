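"""Synthetic multi-batch count data with known structure.

The generator emulates the two features that make batch integration hard
in real single-cell count data: per-cell sequencing-depth differences
between batches and per-batch gene-wise distortions, layered on top of
genuine cell-type structure. Counts are negative-binomial with a
mean/dispersion parameterization (variance mu + mu^2/theta), followed by
an independent constant-probability dropout mask. A second generator
produces staged differentiation trajectories in which a subset of genes
changes monotonically across stages.

With ``gene_factors`` identically 1 and batches differing only in
``depth_factor``, the batch effect is exactly a per-cell positive
scaling, so total or l2 normalization removes it exactly — the key
recovery scenario used throughout the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix

__all__ = [
    "CellTypeSpec",
    "BatchSpec",
    "SimConfig",
    "TrajectorySimConfig",
    "simulate_counts",
    "simulate_trajectory_counts",
    "make_type_profiles",
    "depth_scaled_scenario",
]


@dataclass
class CellTypeSpec:
    name: str
    n_cells_per_batch: list[int]
    mean_profile: np.ndarray  # per-gene positive means


@dataclass
class BatchSpec:
    name: str
    depth_factor: float = 1.0
    gene_factors: np.ndarray | None = None  # per-gene positive factors; None = all ones


@dataclass
class SimConfig:
    """Configuration for the multi-batch cell-type count generator."""

    n_genes: int
    cell_types: list[CellTypeSpec]
    batches: list[BatchSpec]
    dispersion: float = 2.0
    dropout_prob: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.cell_types or not self.batches:
            raise ValueError("need at least one cell type and one batch")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not (0 <= self.dropout_prob < 1):
            raise ValueError("dropout_prob must be in [0, 1)")
        for ct in self.cell_types:
            if len(ct.n_cells_per_batch) != len(self.batches):
                raise ValueError(
                    f"cell type {ct.name!r} lists {len(ct.n_cells_per_batch)} batch "
                    f"counts but there are {len(self.batches)} batches"
                )
            prof = np.asarray(ct.mean_profile, dtype=float)
            if prof.shape != (self.n_genes,) or np.any(prof <= 0):
                raise ValueError(f"cell type {ct.name!r} needs {self.n_genes} positive means")
        for b in self.batches:
            if b.depth_factor <= 0:
                raise ValueError(f"batch {b.name!r} depth_factor must be positive")
            if b.gene_factors is not None:
                gf = np.asarray(b.gene_factors, dtype=float)
                if gf.shape != (self.n_genes,) or np.any(gf <= 0):
                    raise ValueError(f"batch {b.name!r} needs {self.n_genes} positive gene factors")


@dataclass
class TrajectorySimConfig:
    """Configuration for the staged-trajectory count generator.

    ``effect_size`` is the total fold change of each dynamic gene from
    the first to the last stage; 1 means no dynamics.
    """

    stages: list[str]
    n_cells_per_stage: int
    n_genes: int
    n_dynamic_genes: int
    effect_size: float = 4.0
    dispersion: float = 2.0
    dropout_prob: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("stages must be non-empty")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("stage names must be unique")
        if self.n_cells_per_stage <= 0 or self.n_genes <= 0:
            raise ValueError("cell and gene counts must be positive")
        if not (0 <= self.n_dynamic_genes <= self.n_genes):
            raise ValueError("n_dynamic_genes must be <= n_genes")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if self.dispersion <= 0 or not (0 <= self.dropout_prob < 1):
            raise ValueError("invalid dispersion or dropout_prob")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial counts with mean mu and dispersion theta."""
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p).astype(np.float64)


def simulate_counts(cfg: SimConfig) -> ExpressionMatrix:
    """Draw a multi-batch, multi-cell-type count matrix.

    Counts for a cell of type t in batch b are
    ``NB(mean = depth_b * gene_factors_b * profile_t, dispersion theta)``
    with independent Bernoulli dropout. One sub-stream per batch is
    spawned deterministically from the global seed, so the same seed
    always yields the same matrix.
    """
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(len(cfg.batches))
    blocks: list[np.ndarray] = []
    cell_ids: list[str] = []
    batch_lab: list[str] = []
    type_lab: list[str] = []
    for bi, (batch, ss) in enumerate(zip(cfg.batches, streams)):
        rng = np.random.default_rng(ss)
        gf = (
            np.ones(cfg.n_genes)
            if batch.gene_factors is None
            else np.asarray(batch.gene_factors, dtype=float)
        )
        for ct in cfg.cell_types:
            n = ct.n_cells_per_batch[bi]
            if n == 0:
                continue
            mu = batch.depth_factor * gf * np.asarray(ct.mean_profile, dtype=float)
            counts = _nb_draw(rng, np.broadcast_to(mu, (n, cfg.n_genes)), cfg.dispersion)
            if cfg.dropout_prob > 0:
                counts = counts * (rng.random(counts.shape) >= cfg.dropout_prob)
            blocks.append(counts)
            start = len(cell_ids)
            cell_ids.extend(f"{batch.name}.{ct.name}.{start + i}" for i in range(n))
            batch_lab.extend([batch.name] * n)
            type_lab.extend([ct.name] * n)
    values = np.vstack(blocks)
    meta = pd.DataFrame(
        {"batch": batch_lab, "cell_type": type_lab},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return ExpressionMatrix(values=values, cell_ids=cell_ids, gene_ids=[f"g{j}" for j in range(cfg.n_genes)], meta=meta)


def simulate_trajectory_counts(cfg: TrajectorySimConfig) -> ExpressionMatrix:
    """Draw a staged differentiation trajectory.

    Each dynamic gene's mean changes monotonically across stages with a
    total fold change of ``effect_size`` (half the dynamic genes go up,
    half down); the remaining genes are flat. Metadata carries the stage
    label and a single batch.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    base = rng.lognormal(mean=1.0, sigma=0.5, size=cfg.n_genes) + 0.5
    dyn = rng.choice(cfg.n_genes, size=cfg.n_dynamic_genes, replace=False)
    direction = np.ones(cfg.n_dynamic_genes)
    direction[: cfg.n_dynamic_genes // 2] = -1.0
    S = len(cfg.stages)
    blocks: list[np.ndarray] = []
    cell_ids: list[str] = []
    stage_lab: list[str] = []
    for s, stage in enumerate(cfg.stages):
        frac = s / (S - 1) if S > 1 else 0.0
        mu = base.copy()
        mu[dyn] = base[dyn] * cfg.effect_size ** (direction * frac)
        counts = _nb_draw(
            rng, np.broadcast_to(mu, (cfg.n_cells_per_stage, cfg.n_genes)), cfg.dispersion
        )
        if cfg.dropout_prob > 0:
            counts = counts * (rng.random(counts.shape) >= cfg.dropout_prob)
        blocks.append(counts)
        start = len(cell_ids)
        cell_ids.extend(f"{stage}.{start + i}" for i in range(cfg.n_cells_per_stage))
        stage_lab.extend([stage] * cfg.n_cells_per_stage)
    values = np.vstack(blocks)
    meta = pd.DataFrame(
        {"batch": ["batch0"] * len(cell_ids), "stage": stage_lab},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return ExpressionMatrix(
        values=values,
        cell_ids=cell_ids,
        gene_ids=[f"g{j}" for j in range(cfg.n_genes)],
        meta=meta,
    )


# ---------------------------------------------------------------------------
# convenience scenario builders
# ---------------------------------------------------------------------------


def make_type_profiles(
    n_types: int,
    n_genes: int,
    seed: int = 0,
    base_mean: float = 3.0,
    marker_frac: float = 0.12,
    marker_fold: float = 8.0,
) -> list[np.ndarray]:
    """Build per-type mean profiles: a shared lognormal baseline with a
    disjoint block of up-regulated marker genes per type."""
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=np.log(base_mean), sigma=0.6, size=n_genes) + 0.2
    n_markers = max(1, int(n_genes * marker_frac))
    profiles = []
    for t in range(n_types):
        prof = base.copy()
        lo = (t * n_markers) % n_genes
        idx = (np.arange(n_markers) + lo) % n_genes
        prof[idx] *= marker_fold
        profiles.append(prof)
    return profiles


def depth_scaled_scenario(
    n_types: int = 3,
    n_batches: int = 2,
    cells_per_type_per_batch: int = 100,
    n_genes: int = 200,
    depth_factor: float = 5.0,
    dispersion: float = 2.0,
    dropout_prob: float = 0.2,
    seed: int = 0,
) -> SimConfig:
    """The depth-only batch-effect scenario.

    Batches share gene factors (all ones) and differ only by a per-cell
    depth multiplier (1, depth_factor, depth_factor^2, ...), so the
    batch effect is removable exactly by total or l2 normalization.
    """
    profiles = make_type_profiles(n_types, n_genes, seed=seed)
    cell_types = [
        CellTypeSpec(
            name=f"type{t}",
            n_cells_per_batch=[cells_per_type_per_batch] * n_batches,
            mean_profile=profiles[t],
        )
        for t in range(n_types)
    ]
    batches = [
        BatchSpec(name=f"batch{b}", depth_factor=depth_factor**b) for b in range(n_batches)
    ]
    return SimConfig(
        n_genes=n_genes,
        cell_types=cell_types,
        batches=batches,
        dispersion=dispersion,
        dropout_prob=dropout_prob,
        seed=seed,
    )
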