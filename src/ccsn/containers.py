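"""Core in-memory containers shared across the pipeline.

The pipeline operates on a genes x cells expression matrix (log(1+x)
normalized, nonnegative), a per-cell annotation table (cell type and
condition), per-cell binary gene-gene networks, and a genes x cells
integer degree matrix derived from those networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DegreeMatrix",
    "CellAnnotation",
    "CellNetwork",
    "CsnParams",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


def _check_ids(ids: Sequence[str], n: int, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(ids) != n:
        raise ValidationError(f"{what}: expected {n} ids, got {len(ids)}")
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValidationError(f"{what}: duplicate ids {sorted(set(dups))[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x cells matrix of nonnegative, log(1+x)-scale expression values."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D genes x cells array")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain NaN or infinite entries")
        if np.any(self.values < 0):
            raise ValidationError("expression values must be nonnegative")
        self.gene_ids = _check_ids(self.gene_ids, self.values.shape[0], "gene_ids")
        self.cell_ids = _check_ids(self.cell_ids, self.values.shape[1], "cell_ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def subset_cells(self, cell_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = list(cell_ids)
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in wanted if c not in pos]
        if missing:
            raise ValidationError(f"unknown cell ids: {missing[:5]}")
        idx = [pos[c] for c in wanted]
        return ExpressionMatrix(self.values[:, idx], list(self.gene_ids), wanted)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class DegreeMatrix:
    """Genes x cells matrix of per-cell network degrees (the CNDM).

    Entry (g, k) is the degree of gene g in cell k's conditional
    cell-specific network; gene/cell ordering matches the source
    expression matrix.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D genes x cells array")
        if not np.issubdtype(self.values.dtype, np.integer):
            rounded = np.rint(self.values)
            if not np.allclose(self.values, rounded):
                raise ValidationError("degrees must be integers")
            self.values = rounded.astype(np.int64)
        if np.any(self.values < 0):
            raise ValidationError("degrees must be nonnegative")
        self.gene_ids = _check_ids(self.gene_ids, self.values.shape[0], "gene_ids")
        self.cell_ids = _check_ids(self.cell_ids, self.values.shape[1], "cell_ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, cell_ids: Iterable[str]) -> "DegreeMatrix":
        wanted = list(cell_ids)
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in wanted if c not in pos]
        if missing:
            raise ValidationError(f"unknown cell ids: {missing[:5]}")
        idx = [pos[c] for c in wanted]
        return DegreeMatrix(self.values[:, idx], list(self.gene_ids), wanted)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class CellAnnotation:
    """Cell metadata: one row per cell with its cell type and condition."""

    table: pd.DataFrame

    REQUIRED = ("cell_id", "cell_type", "condition")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation missing columns {missing}")
        self.table = self.table.reset_index(drop=True)
        self.table["cell_id"] = self.table["cell_id"].astype(str)
        if self.table["cell_id"].duplicated().any():
            dups = self.table.loc[self.table["cell_id"].duplicated(), "cell_id"]
            raise ValidationError(f"duplicate cell ids in annotation: {list(dups)[:5]}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table["cell_id"])

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    def cells_of(self, cell_type: str | None = None, condition: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if cell_type is not None:
            mask &= self.table["cell_type"] == cell_type
        if condition is not None:
            mask &= self.table["condition"] == condition
        return list(self.table.loc[mask, "cell_id"])

    def label_of(self, column: str, cell_ids: Sequence[str]) -> np.ndarray:
        lookup = self.table.set_index("cell_id")[column]
        return lookup.loc[list(cell_ids)].to_numpy()


@dataclass
class CellNetwork:
    """One cell's binary gene-gene association network, stored as an edge list.

    Edges are unordered gene-index pairs (i < j); the adjacency is
    symmetric with a zero diagonal.
    """

    cell_id: str
    n_genes: int
    edges: np.ndarray  # shape (E, 2), int, i < j, lexicographically sorted

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if e.size:
            if np.any(e < 0) or np.any(e >= self.n_genes):
                raise ValidationError("edge gene index out of range")
            if np.any(e[:, 0] >= e[:, 1]):
                raise ValidationError("edges must satisfy i < j (no self-loops)")
            order = np.lexsort((e[:, 1], e[:, 0]))
            e = e[order]
        self.edges = e

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_genes, dtype=np.int64)
        if self.edges.size:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_genes, self.n_genes), dtype=bool)
        if self.edges.size:
            a[self.edges[:, 0], self.edges[:, 1]] = True
            a[self.edges[:, 1], self.edges[:, 0]] = True
        return a

    @classmethod
    def from_adjacency(cls, cell_id: str, adj: np.ndarray) -> "CellNetwork":
        adj = np.asarray(adj, dtype=bool)
        if adj.shape[0] != adj.shape[1]:
            raise ValidationError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(adj)):
            raise ValidationError("adjacency must have a zero diagonal")
        i, j = np.nonzero(np.triu(adj, k=1))
        return cls(cell_id, adj.shape[0], np.column_stack([i, j]))


@dataclass
class CsnParams:
    """Tuning parameters of the per-cell network construction.

    box_fraction
        Fraction of cells in each gene's value-nearest neighborhood box.
        The default 0.3 keeps the normal approximation of the overlap
        statistic calibrated at a few hundred cells (see docs/methods.md);
        smaller boxes are more cell-specific but anti-conservative.
    alpha
        Significance level of the one-sided normal test on the overlap
        statistic; an edge is drawn when the statistic exceeds the upper
        alpha quantile of N(0, 1).
    n_conditional
        Number of top-degree "conditional" genes per cell used to re-test
        associations; 0 disables conditioning (plain cell-specific network).
    min_expressing_cells
        Genes expressed (value > 0) in fewer cells are excluded from
        network construction.
    conditional_agg
        How statistics over multiple conditional genes are combined:
        "mean" (default) or "min".
    """

    box_fraction: float = 0.3
    alpha: float = 0.01
    n_conditional: int = 1
    min_expressing_cells: int = 10
    conditional_agg: str = "mean"

    def __post_init__(self) -> None:
        if not 0.0 < self.box_fraction < 1.0:
            raise ValidationError("box_fraction must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.n_conditional < 0:
            raise ValidationError("n_conditional must be >= 0")
        if self.min_expressing_cells < 0:
            raise ValidationError("min_expressing_cells must be >= 0")
        if self.conditional_agg not in ("mean", "min"):
            raise ValidationError("conditional_agg must be 'mean' or 'min'")
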