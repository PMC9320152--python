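"""Differential analysis of expression and network degree; 'dark' genes.

A dark gene shows no significant expression difference between the two
conditions (Welch t-test, p > 0.05) yet a significant difference in its
per-cell network degree (Welch t-test, Benjamini-Hochberg FDR < 0.05).
Such genes are invisible to ordinary differential expression but change
their position in the gene association network between conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CellAnnotation, DegreeMatrix, ExpressionMatrix, ValidationError

__all__ = [
    "welch_t",
    "bh_fdr",
    "differential_table",
    "find_dark_genes",
    "hypergeom_enrichment",
    "DarkGene",
    "GeneSetCollection",
    "read_gmt",
]

logger = logging.getLogger(__name__)

_TINY = float(np.finfo(float).tiny)


@dataclass
class DarkGene:
    gene: str
    cell_type: str
    expression_p: float
    degree_fdr: float
    direction: str  # which condition has the higher mean degree


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) plus the testing universe."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, description, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if genes:
                sets[name] = set(genes)
                desc[name] = description
    return GeneSetCollection(sets, desc)


def welch_t(values_a: np.ndarray, values_b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p value.

    Zero variance in both groups: equal means give (0, 1) — no evidence;
    unequal means give a p clipped to the smallest positive float, with
    the t statistic signed by the mean difference.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), _TINY
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_table(
    matrix: ExpressionMatrix | DegreeMatrix,
    annotation: CellAnnotation,
    layer: str,
    cell_type: str,
    conditions: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene Welch t-tests between the two conditions within one cell type.

    ``layer`` labels the matrix being compared ("expression" for the GEM,
    "degree" for the CNDM).  Returns a DataFrame with columns (gene,
    layer, mean_<ref>, mean_<dis>, t, p, fdr); BH adjustment spans the
    genes tested in this comparison.
    """
    if layer not in ("expression", "degree"):
        raise ValidationError("layer must be 'expression' or 'degree'")
    conds = list(conditions) if conditions else annotation.conditions
    if len(conds) != 2:
        raise ValidationError(f"need exactly 2 conditions, have {conds}")
    ref, dis = conds
    groups = {}
    for cond in (ref, dis):
        cells = annotation.cells_of(cell_type=cell_type, condition=cond)
        if len(cells) < 2:
            raise ValidationError(
                f"condition {cond!r} has {len(cells)} cells of type {cell_type!r} (need >= 2)"
            )
        groups[cond] = matrix.subset_cells(cells).values.astype(float)
    A, B = groups[ref], groups[dis]
    t = np.empty(A.shape[0])
    p = np.empty(A.shape[0])
    # vectorized Welch with row-wise zero-variance handling
    res = stats.ttest_ind(A, B, axis=1, equal_var=False)
    t[:], p[:] = res.statistic, res.pvalue
    var0 = (A.var(axis=1, ddof=1) == 0) & (B.var(axis=1, ddof=1) == 0)
    if var0.any():
        same = var0 & (A.mean(axis=1) == B.mean(axis=1))
        diff = var0 & ~same
        t[same], p[same] = 0.0, 1.0
        t[diff] = np.sign(A.mean(axis=1) - B.mean(axis=1))[diff] * np.inf
        p[diff] = _TINY
    table = pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "layer": layer,
            f"mean_{ref}": A.mean(axis=1),
            f"mean_{dis}": B.mean(axis=1),
            "t": t,
            "p": p,
            "fdr": bh_fdr(p),
        }
    )
    return table


def find_dark_genes(
    expr_diff: pd.DataFrame,
    degree_diff: pd.DataFrame,
    cell_type: str = "",
    p_expr: float = 0.05,
    fdr_degree: float = 0.05,
) -> list[DarkGene]:
    """Genes with expression p > ``p_expr`` and degree FDR < ``fdr_degree``.

    Both tables must cover the same gene universe (any row order).  The
    direction records which condition has the higher mean degree.
    """
    e = expr_diff.set_index("gene")
    d = degree_diff.set_index("gene")
    if set(e.index) != set(d.index):
        raise ValidationError("expression and degree tables cover different gene universes")
    d = d.loc[e.index]
    mean_cols = [c for c in d.columns if c.startswith("mean_")]
    if len(mean_cols) != 2:
        raise ValidationError("degree table must have exactly 2 mean_<condition> columns")
    ref_col, dis_col = mean_cols
    mask = (e["p"] > p_expr) & (d["fdr"] < fdr_degree)
    out = []
    for gene in e.index[mask]:
        higher = dis_col if d.loc[gene, dis_col] > d.loc[gene, ref_col] else ref_col
        out.append(
            DarkGene(
                gene=str(gene),
                cell_type=cell_type,
                expression_p=float(e.loc[gene, "p"]),
                degree_fdr=float(d.loc[gene, "fdr"]),
                direction=higher.removeprefix("mean_"),
            )
        )
    return out


def hypergeom_enrichment(
    query_genes,
    collection: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    Query genes outside the universe are dropped (logged); set members
    are intersected with the universe before testing.  Returns a
    DataFrame (set, description, set_size, overlap, p, fdr) sorted by p.
    """
    universe = set(map(str, universe))
    query = set(map(str, query_genes))
    dropped = query - universe
    if dropped:
        logger.info("dropping %d query genes outside the universe", len(dropped))
    query &= universe
    if not query:
        raise ValidationError("query is empty after restriction to the universe")
    M, N = len(universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        members = members & universe
        if not members:
            continue
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if k > 0 else 1.0
        rows.append(
            {
                "set": name,
                "description": collection.descriptions.get(name, ""),
                "set_size": K,
                "overlap": k,
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["fdr"] = bh_fdr(table["p"].to_numpy())
        table = table.sort_values("p").reset_index(drop=True)
    return table
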