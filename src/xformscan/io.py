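"""Reading count matrices and metadata; writing result tables.

Accepted matrix formats are Matrix Market (``.mtx``) and delimited text
(TSV/CSV). Matrix Market input is assumed genes x cells (the upstream
convention) and is transposed to cells x genes on read; dense delimited
matrices are taken as written, cells in rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .datamodel import ExpressionMatrix

__all__ = ["read_counts", "write_results", "read_results", "write_manifest"]


def _read_id_list(path: str | Path) -> list[str]:
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    return ids


def read_counts(
    matrix_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
    meta_path: str | Path,
    batch_col: str = "batch",
    cell_type_col: str | None = "cell_type",
    stage_col: str | None = "stage",
) -> ExpressionMatrix:
    """Read a count matrix plus id lists and per-cell metadata.

    Parameters
    ----------
    matrix_path
        ``.mtx`` (genes x cells, transposed on read) or delimited text
        (cells x rows, no header).
    cells_path, genes_path
        One identifier per line (first column of a TSV).
    meta_path
        TSV with a header; first column is the cell id. The column named
        ``batch_col`` is required and renamed to ``batch`` internally;
        ``cell_type_col`` / ``stage_col`` are picked up when present.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        mat = scipy.io.mmread(matrix_path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=np.float64).T  # genes x cells -> cells x genes
    else:
        sep = "," if matrix_path.suffix == ".csv" else "\t"
        values = pd.read_csv(matrix_path, sep=sep, header=None).to_numpy(dtype=np.float64)

    cell_ids = _read_id_list(cells_path)
    gene_ids = _read_id_list(genes_path)
    if values.shape != (len(cell_ids), len(gene_ids)):
        raise ValueError(
            f"matrix shape {values.shape} does not match "
            f"{len(cell_ids)} cells x {len(gene_ids)} genes"
        )
    if np.any(values < 0):
        raise ValueError("negative entry in count matrix")

    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    rename: dict[str, str] = {}
    if batch_col not in meta.columns:
        raise ValueError(f"metadata has no batch column {batch_col!r}")
    rename[batch_col] = "batch"
    if cell_type_col and cell_type_col in meta.columns:
        rename[cell_type_col] = "cell_type"
    if stage_col and stage_col in meta.columns:
        rename[stage_col] = "stage"
    meta = meta.rename(columns=rename)

    return ExpressionMatrix(values=values, cell_ids=cell_ids, gene_ids=gene_ids, meta=meta)


def write_results(table, path: str | Path) -> None:
    """Write a grid-result table to CSV (one row per pipeline cell).

    Numbers round-trip to better than 1e-12 (full ``repr`` precision);
    identifiers round-trip exactly.
    """
    df = table.to_dataframe() if hasattr(table, "to_dataframe") else table
    if len(df) == 0:
        raise ValueError("refusing to write an empty result table")
    df.to_csv(path, index=False, float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(manifest: dict, path: str | Path) -> None:
    """Write the run manifest (configuration + seeds) as JSON."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
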