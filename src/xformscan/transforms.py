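"""Elementary data transformations and their composition into chains.

Six statistics are supported: raw (identity), total-count normalization
(``e / sum(e) * target_sum``), ``log2(e + 1)``, l2 normalization
(``e / sqrt(sum(e^2))``), min-max scaling (``(e - min) / (max - min)``)
and z-scoring (``(e - mean) / std``). Total and l2 act per cell;
min-max and z-score default to per gene (the standardization convention
popularized by Seurat) but accept either axis.

A chain composes these left to right under a fixed grammar::

    [total] -> [log2] -> [one of l2norm | minmax | zscore]

Every subset of that grammar is valid, giving 2 x 2 x 4 = 16 chains,
from the empty chain ("raw") to "total_log2_zscore".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .datamodel import ExpressionMatrix

__all__ = [
    "TransformStep",
    "TransformChain",
    "apply_total",
    "apply_log2",
    "apply_l2norm",
    "apply_minmax",
    "apply_zscore",
    "apply_chain",
    "enumerate_chains",
    "DEFAULT_TARGET_SUM",
]

DEFAULT_TARGET_SUM = 20000.0

Kind = Literal["total", "log2", "l2norm", "minmax", "zscore"]
Axis = Literal["per_cell", "per_gene"]

_DEFAULT_AXIS: dict[str, str] = {
    "total": "per_cell",
    "l2norm": "per_cell",
    "minmax": "per_gene",
    "zscore": "per_gene",
    "log2": "per_cell",  # elementwise; axis is irrelevant
}
# grammar position: total before log2 before the final scaler
_ORDER: dict[str, int] = {"total": 0, "log2": 1, "l2norm": 2, "minmax": 2, "zscore": 2}
_SCALERS = ("l2norm", "minmax", "zscore")


@dataclass(frozen=True)
class TransformStep:
    """One transformation statistic with its axis and parameters."""

    kind: Kind
    axis: Axis = None  # type: ignore[assignment]
    target_sum: float = DEFAULT_TARGET_SUM

    def __post_init__(self):
        if self.kind not in _ORDER:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.axis is None:
            object.__setattr__(self, "axis", _DEFAULT_AXIS[self.kind])
        if self.axis not in ("per_cell", "per_gene"):
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.target_sum <= 0:
            raise ValueError("target_sum must be positive")


@dataclass(frozen=True)
class TransformChain:
    """An ordered, validated sequence of transformation steps.

    The empty chain is named ``"raw"``; otherwise the name joins step
    kinds with underscores, e.g. ``"total_log2_zscore"``.
    """

    steps: tuple[TransformStep, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "steps", tuple(self.steps))
        kinds = [s.kind for s in self.steps]
        if len(set(kinds)) != len(kinds):
            raise ValueError(f"chain repeats a step kind: {kinds}")
        order = [_ORDER[k] for k in kinds]
        if order != sorted(order):
            raise ValueError(
                f"invalid step order {kinds}: grammar is total -> log2 -> scaler"
            )
        n_scalers = sum(k in _SCALERS for k in kinds)
        if n_scalers > 1:
            raise ValueError(f"at most one final scaler allowed, got {kinds}")
        # log2 requires nonnegative input; everything the grammar allows
        # before it (total) preserves nonnegativity, so ordering suffices.

    @property
    def name(self) -> str:
        if not self.steps:
            return "raw"
        return "_".join(s.kind for s in self.steps)

    @classmethod
    def from_name(
        cls,
        name: str,
        target_sum: float = DEFAULT_TARGET_SUM,
        minmax_axis: Axis = "per_gene",
        zscore_axis: Axis = "per_gene",
    ) -> "TransformChain":
        """Parse a chain name like ``"total_log2_zscore"`` or ``"raw"``."""
        name = name.strip().lower()
        if name in ("", "raw"):
            return cls(())
        steps = []
        for kind in name.split("_"):
            if kind == "minmax":
                steps.append(TransformStep("minmax", axis=minmax_axis))
            elif kind == "zscore":
                steps.append(TransformStep("zscore", axis=zscore_axis))
            elif kind == "total":
                steps.append(TransformStep("total", target_sum=target_sum))
            else:
                steps.append(TransformStep(kind))  # type: ignore[arg-type]
        return cls(tuple(steps))

    def __str__(self) -> str:
        return self.name


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def _as_values(X) -> np.ndarray:
    return X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)


def _wrap(X, values: np.ndarray):
    return X.with_values(values) if isinstance(X, ExpressionMatrix) else values


def apply_total(X, target_sum: float = DEFAULT_TARGET_SUM):
    """Per-cell total-count normalization: ``e / sum(e) * target_sum``."""
    V = _as_values(X)
    sums = V.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        ids = (
            [X.cell_ids[i] for i in zero[:10]]
            if isinstance(X, ExpressionMatrix)
            else zero[:10].tolist()
        )
        raise ValueError(f"zero-sum cells cannot be total-normalized: {ids}")
    return _wrap(X, V / sums[:, None] * target_sum)


def apply_log2(X):
    """Elementwise ``log2(e + 1)``; input must be nonnegative."""
    V = _as_values(X)
    if np.any(V < 0):
        raise ValueError("log2 transform requires nonnegative input (invalid chain order?)")
    return _wrap(X, np.log2(V + 1.0))


def apply_l2norm(X):
    """Per-cell scaling to unit euclidean norm: ``e / sqrt(sum(e^2))``."""
    V = _as_values(X)
    norms = np.linalg.norm(V, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        ids = (
            [X.cell_ids[i] for i in zero[:10]]
            if isinstance(X, ExpressionMatrix)
            else zero[:10].tolist()
        )
        raise ValueError(f"zero-norm cells cannot be l2-normalized: {ids}")
    return _wrap(X, V / norms[:, None])


def _axis_index(axis: Axis) -> int:
    # per_cell statistics run along genes (axis=1); per_gene along cells (axis=0)
    return 1 if axis == "per_cell" else 0


def apply_minmax(X, axis: Axis = "per_gene"):
    """Min-max scaling to [0, 1] along ``axis``; constant vectors map to 0."""
    V = _as_values(X)
    ax = _axis_index(axis)
    lo = V.min(axis=ax, keepdims=True)
    hi = V.max(axis=ax, keepdims=True)
    rng = hi - lo
    out = np.where(rng > 0, (V - lo) / np.where(rng > 0, rng, 1.0), 0.0)
    return _wrap(X, out)


def apply_zscore(X, axis: Axis = "per_gene"):
    """Standardization ``(e - mean(e)) / std(e)`` along ``axis``.

    Population standard deviation (divide by n). Constant vectors map to
    all-zeros rather than dividing by zero.
    """
    V = _as_values(X)
    ax = _axis_index(axis)
    mu = V.mean(axis=ax, keepdims=True)
    sd = V.std(axis=ax, keepdims=True)  # population std
    # constancy detected via exact max==min: for a constant vector the
    # computed std can be float noise rather than exactly zero
    varying = (V.max(axis=ax, keepdims=True) > V.min(axis=ax, keepdims=True)) & (sd > 0)
    out = np.where(varying, (V - mu) / np.where(varying, sd, 1.0), 0.0)
    return _wrap(X, out)


def _apply_step(X, step: TransformStep):
    if step.kind == "total":
        return apply_total(X, step.target_sum)
    if step.kind == "log2":
        return apply_log2(X)
    if step.kind == "l2norm":
        return apply_l2norm(X)
    if step.kind == "minmax":
        return apply_minmax(X, step.axis)
    if step.kind == "zscore":
        return apply_zscore(X, step.axis)
    raise ValueError(step.kind)


def apply_chain(X, chain: TransformChain):
    """Apply a chain's steps left to right; the empty chain copies."""
    if isinstance(chain, str):
        chain = TransformChain.from_name(chain)
    if not chain.steps:
        V = _as_values(X)
        return _wrap(X, V.copy())
    out = X
    for i, step in enumerate(chain.steps):
        try:
            out = _apply_step(out, step)
        except ValueError as exc:
            raise ValueError(f"step {i} ({step.kind}) of chain {chain.name!r}: {exc}") from exc
    return out


def enumerate_chains(
    target_sum: float = DEFAULT_TARGET_SUM,
    minmax_axis: Axis = "per_gene",
    zscore_axis: Axis = "per_gene",
) -> list[TransformChain]:
    """Enumerate the full chain grammar: 16 chains, sorted by name.

    The grammar is the product {total?} x {log2?} x {none, l2norm,
    minmax, zscore}; it includes the empty chain ("raw") and the
    Seurat-style "total_log2_zscore".
    """
    chains = []
    for use_total in (False, True):
        for use_log2 in (False, True):
            for scaler in (None, "l2norm", "minmax", "zscore"):
                steps: list[TransformStep] = []
                if use_total:
                    steps.append(TransformStep("total", target_sum=target_sum))
                if use_log2:
                    steps.append(TransformStep("log2"))
                if scaler == "minmax":
                    steps.append(TransformStep("minmax", axis=minmax_axis))
                elif scaler == "zscore":
                    steps.append(TransformStep("zscore", axis=zscore_axis))
                elif scaler == "l2norm":
                    steps.append(TransformStep("l2norm"))
                chains.append(TransformChain(tuple(steps)))
    return sorted(chains, key=lambda c: c.name)
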