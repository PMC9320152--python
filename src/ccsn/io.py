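"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV (genes as rows, cell-id header) or as
a MatrixMarket triplet (matrix.mtx + rows.txt + cols.txt); annotations,
degree matrices, edge lists and survival tables as TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import CellAnnotation, CellNetwork, DegreeMatrix, ExpressionMatrix, ValidationError

__all__ = [
    "read_expression",
    "write_expression",
    "read_expression_mtx",
    "write_expression_mtx",
    "read_annotation",
    "write_annotation",
    "read_degree_matrix",
    "write_degree_matrix",
    "write_edge_list",
    "write_network",
    "read_survival",
    "write_survival",
]


def read_expression(path, normalize_log1p: bool = False) -> ExpressionMatrix:
    """Read a genes x cells TSV (gene rows, cell-id header).

    ``normalize_log1p`` applies log(1 + x) to raw nonnegative input.
    Duplicate ids, NaN and negative entries are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"duplicate cell id {dup!r} in {path}")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        g, c = np.argwhere(np.isnan(values))[0]
        raise ValidationError(f"NaN at gene {df.index[g]!r}, cell {df.columns[c]!r} in {path}")
    if (values < 0).any():
        g, c = np.argwhere(values < 0)[0]
        raise ValidationError(f"negative value at gene {df.index[g]!r}, cell {df.columns[c]!r}")
    if normalize_log1p:
        values = np.log1p(values)
    return ExpressionMatrix(values, list(df.index.astype(str)), list(df.columns.astype(str)))


def write_expression(expr: ExpressionMatrix, path) -> None:
    df = expr.to_dataframe()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_expression_mtx(mtx_path, rows_path, cols_path,
                        normalize_log1p: bool = False) -> ExpressionMatrix:
    """Read a MatrixMarket triplet: .mtx plus row (gene) and column (cell) id files."""
    mat = scipy.io.mmread(mtx_path)
    values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    genes = Path(rows_path).read_text().split()
    cells = Path(cols_path).read_text().split()
    if normalize_log1p:
        values = np.log1p(values)
    return ExpressionMatrix(values, genes, cells)


def write_expression_mtx(expr: ExpressionMatrix, mtx_path, rows_path, cols_path) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(expr.values))
    Path(rows_path).write_text("\n".join(expr.gene_ids) + "\n")
    Path(cols_path).write_text("\n".join(expr.cell_ids) + "\n")


def read_annotation(path) -> CellAnnotation:
    return CellAnnotation(pd.read_csv(path, sep="\t", dtype=str))


def write_annotation(annotation: CellAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_degree_matrix(path) -> DegreeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DegreeMatrix(df.to_numpy(), list(df.index.astype(str)), list(df.columns.astype(str)))


def write_degree_matrix(dm: DegreeMatrix, path) -> None:
    df = dm.to_dataframe()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def write_edge_list(network: CellNetwork, gene_ids, path) -> None:
    """Per-cell network as a two-column TSV of gene-id pairs."""
    rows = [(gene_ids[i], gene_ids[j]) for i, j in network.edges]
    pd.DataFrame(rows, columns=["gene_i", "gene_j"]).to_csv(path, sep="\t", index=False)


def write_network(graph, path) -> None:
    """Weighted aggregated network as (source, target, weight) TSV."""
    rows = [(u, v, d.get("weight", 1.0)) for u, v, d in sorted(graph.edges(data=True))]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    if not required.issubset(df.columns):
        raise ValidationError(f"survival table must have columns {sorted(required)}")
    if (df["time"] <= 0).any():
        raise ValidationError("survival times must be strictly positive")
    if not set(df["event"].unique()) <= {0, 1}:
        raise ValidationError("event flags must be 0 or 1")
    return df


def write_survival(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
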