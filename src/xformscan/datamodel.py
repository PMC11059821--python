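"""Shared data model: the cells-by-genes expression matrix.

Cells are rows and genes are columns everywhere in this package, so each
row is one cell's expression vector. Matrix Market files, which
conventionally store genes-by-cells, are transposed on read (see
:mod:`xformscan.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """A cells x genes expression matrix with per-cell metadata.

    Parameters
    ----------
    values
        Dense float array of shape ``(n_cells, n_genes)``; all entries
        finite, raw input nonnegative.
    cell_ids
        Unique cell identifiers, one per row.
    gene_ids
        Unique gene identifiers, one per column.
    meta
        Per-cell metadata indexed by cell id. Must contain a ``batch``
        column with no missing values; ``cell_type`` and ``stage`` are
        optional.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n_cells} rows but {len(self.cell_ids)} cell ids"
            )
        if n_genes != len(self.gene_ids):
            raise ValueError(
                f"matrix has {n_genes} columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite entries")
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            self.meta = self.meta.copy()
            self.meta.index = self.meta.index.astype(str)
            missing = [c for c in self.cell_ids if c not in self.meta.index]
            if missing:
                raise ValueError(f"metadata missing cell ids: {missing[:5]}")
            self.meta = self.meta.loc[self.cell_ids]
        if "batch" in self.meta.columns and self.meta["batch"].isna().any():
            bad = list(self.meta.index[self.meta["batch"].isna()][:5])
            raise ValueError(f"cells missing batch label: {bad}")

    # -- convenience accessors -------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def batches(self) -> pd.Series:
        if "batch" not in self.meta.columns:
            raise KeyError("metadata has no 'batch' column")
        return self.meta["batch"]

    def labels(self, column: str = "cell_type") -> pd.Series | None:
        """Return a metadata column as labels, or None if absent."""
        if column in self.meta.columns and not self.meta[column].isna().all():
            return self.meta[column]
        return None

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Copy carrying new values but the same ids and metadata."""
        return ExpressionMatrix(
            values=values,
            cell_ids=list(self.cell_ids),
            gene_ids=list(self.gene_ids),
            meta=self.meta,
        )

    def validate_nonnegative(self) -> None:
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative entry at cell {self.cell_ids[i]!r}, gene {self.gene_ids[j]!r}"
            )
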