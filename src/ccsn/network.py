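"""Cell-specific and conditional cell-specific network construction.

For each cell k, every gene g defines a neighborhood box: the
``ceil(a * n)`` cells whose expression of g is nearest to cell k's value
(cell k itself included).  Two genes are associated in cell k when their
boxes overlap more than chance predicts, measured by a standardized
overlap count that is asymptotically standard normal under independence.
Conditioning on the cell's highest-degree gene(s) re-tests each pair
inside the conditional gene's box, which removes indirect associations
mediated by that gene.  Stacking per-cell degrees over all cells yields
the conditional network degree matrix (CNDM), a genes x cells analogue
of the expression matrix that downstream differential analysis consumes.

All overlap counts are taken over the n - 1 cells other than the focal
cell: cell k belongs to every one of its own boxes by construction, so
its co-membership carries no evidence of association, and excluding it
centres the statistic under the null.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.stats import norm

from .containers import (
    CellNetwork,
    CsnParams,
    DegreeMatrix,
    ExpressionMatrix,
    ValidationError,
)

__all__ = [
    "neighborhood",
    "csn_statistic",
    "ccsn_statistic",
    "build_csn",
    "build_ccsn",
    "select_conditional_genes",
    "compute_cndm",
    "aggregate_networks",
]

logger = logging.getLogger(__name__)


def neighborhood(values: np.ndarray, k: int, box_fraction: float) -> np.ndarray:
    """Indices of the ``ceil(a * n)`` cells nearest in value to cell k.

    Nearness is absolute value distance; ties are broken by ascending
    cell index, which makes the box deterministic even for genes with
    many identical (e.g. zero) values.  Cell k is always a member.

    Returns a sorted integer index array of size exactly ``ceil(a * n)``.
    """
    values = np.asarray(values, dtype=float).ravel()
    n = values.size
    if n < 2:
        raise ValidationError("need at least 2 cells")
    if not 0.0 < box_fraction < 1.0:
        raise ValidationError("box_fraction must lie in (0, 1)")
    if not 0 <= k < n:
        raise IndexError(f"cell index {k} out of range for {n} cells")
    q = math.ceil(box_fraction * n)
    dist = np.abs(values - values[k])
    # stable sort == (distance, cell index) lexicographic order
    order = np.argsort(dist, kind="stable")
    return np.sort(order[:q])


def csn_statistic(n_x: int, n_y: int, n_xy: int, n: int) -> float:
    """Standardized neighborhood-overlap statistic for one gene pair.

    ``(n * n_xy - n_x * n_y) / sqrt(n_x * n_y * (n - n_x) * (n - n_y) / (n - 1))``;
    0 when the denominator vanishes (a box that is empty or covers all
    cells carries no information).  Asymptotically N(0, 1) when the two
    genes are independent.
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    for name, v in (("n_x", n_x), ("n_y", n_y), ("n_xy", n_xy)):
        if v < 0:
            raise ValidationError(f"{name} must be nonnegative")
    if n_x > n or n_y > n:
        raise ValidationError("box sizes cannot exceed n")
    if n_xy > min(n_x, n_y):
        raise ValidationError("overlap n_xy cannot exceed min(n_x, n_y)")
    den_sq = n_x * n_y * (n - n_x) * (n - n_y) / (n - 1)
    if den_sq <= 0:
        return 0.0
    return (n * n_xy - n_x * n_y) / math.sqrt(den_sq)


def ccsn_statistic(n_z: int, n_xz: int, n_yz: int, n_xyz: int) -> float:
    """Conditional overlap statistic computed inside gene z's box.

    Identical in form to :func:`csn_statistic` with the conditional
    gene's box playing the role of the cell universe: counts are box
    overlaps restricted to the n_z cells of z's neighborhood.
    """
    if n_z < 2:
        raise ValidationError("n_z must be >= 2")
    for name, v in (("n_xz", n_xz), ("n_yz", n_yz), ("n_xyz", n_xyz)):
        if v < 0:
            raise ValidationError(f"{name} must be nonnegative")
    if n_xz > n_z or n_yz > n_z:
        raise ValidationError("restricted box sizes cannot exceed n_z")
    if n_xyz > min(n_xz, n_yz):
        raise ValidationError("overlap n_xyz cannot exceed min(n_xz, n_yz)")
    den_sq = n_xz * n_yz * (n_z - n_xz) * (n_z - n_yz) / (n_z - 1)
    if den_sq <= 0:
        return 0.0
    return (n_z * n_xyz - n_xz * n_yz) / math.sqrt(den_sq)


def _tested_genes(expr: ExpressionMatrix, params: CsnParams) -> np.ndarray:
    """Boolean mask of genes passing the expression filter."""
    expressing = (expr.values > 0).sum(axis=1)
    return expressing >= params.min_expressing_cells


def _membership(expr: ExpressionMatrix, k: int, box_fraction: float) -> np.ndarray:
    """Boolean genes x cells matrix: M[g, c] = cell c in gene g's box at cell k."""
    V = expr.values
    n = V.shape[1]
    q = math.ceil(box_fraction * n)
    dist = np.abs(V - V[:, [k]])
    order = np.argsort(dist, axis=1, kind="stable")[:, :q]
    M = np.zeros(V.shape, dtype=bool)
    np.put_along_axis(M, order, True, axis=1)
    return M


def _pair_statistics(M: np.ndarray, k: int, n: int) -> np.ndarray:
    """Dense gene x gene matrix of overlap statistics for one cell.

    Overlaps are counted over the n - 1 cells other than k; every box
    then contains exactly q - 1 of those cells, so the null overlap is
    hypergeometric with identical margins for all pairs.
    """
    cols = np.ones(n, dtype=bool)
    cols[k] = False
    Mk = M[:, cols]
    q1 = int(Mk[0].sum())  # q - 1, identical for every gene
    O = (Mk.astype(np.float32) @ Mk.astype(np.float32).T).astype(float)
    N = n - 1
    den_sq = q1 * q1 * (N - q1) * (N - q1) / (N - 1)
    if den_sq <= 0:
        return np.zeros_like(O)
    return (N * O - q1 * q1) / math.sqrt(den_sq)


def build_csn(expr: ExpressionMatrix, k: int, params: CsnParams | None = None) -> CellNetwork:
    """Build cell k's (unconditional) cell-specific network.

    An edge joins genes x and y when their box-overlap statistic exceeds
    the upper ``alpha`` quantile of the standard normal.  Genes failing
    the expression filter are isolated.
    """
    params = params or CsnParams()
    if not 0 <= k < expr.n_cells:
        raise IndexError(f"cell index {k} out of range")
    tested = _tested_genes(expr, params)
    cell_id = expr.cell_ids[k]
    if tested.sum() < 2:
        logger.warning("cell %s: fewer than 2 genes pass the expression filter", cell_id)
        return CellNetwork(cell_id, expr.n_genes, np.empty((0, 2), dtype=np.int64))
    z_crit = norm.ppf(1.0 - params.alpha)
    M = _membership(expr, k, params.box_fraction)
    stat = _pair_statistics(M, k, expr.n_cells)
    adj = stat > z_crit
    adj &= np.outer(tested, tested)
    np.fill_diagonal(adj, False)
    i, j = np.nonzero(np.triu(adj, k=1))
    return CellNetwork(cell_id, expr.n_genes, np.column_stack([i, j]))


def select_conditional_genes(csn: CellNetwork, m: int) -> list[int]:
    """The m highest-degree genes of a cell's network, ties by gene index.

    Genes of degree zero are never selected; fewer than m genes are
    returned when the network has fewer connected genes.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    deg = csn.degrees()
    nonzero = np.nonzero(deg > 0)[0]
    if nonzero.size == 0:
        return []
    order = sorted(nonzero, key=lambda g: (-deg[g], g))
    return [int(g) for g in order[:m]]


def _conditional_statistics(M: np.ndarray, k: int, z_gene: int) -> np.ndarray:
    """Gene x gene conditional statistics inside gene z's box (minus cell k)."""
    cols = M[z_gene].copy()
    cols[k] = False
    n_z = int(cols.sum())
    G = M.shape[0]
    if n_z < 2:
        return np.zeros((G, G))
    Mz = M[:, cols].astype(np.float32)
    n_xz = Mz.sum(axis=1).astype(float)
    O = (Mz @ Mz.T).astype(float)
    den_sq = np.outer(n_xz, n_xz) * np.outer(n_z - n_xz, n_z - n_xz) / (n_z - 1)
    num = n_z * O - np.outer(n_xz, n_xz)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(den_sq > 0, num / np.sqrt(den_sq), 0.0)
    return stat


def build_ccsn(expr: ExpressionMatrix, k: int, params: CsnParams | None = None) -> CellNetwork:
    """Build cell k's conditional cell-specific network.

    The cell's CSN supplies the ``n_conditional`` top-degree conditional
    genes.  Conditioning prunes: a pair not involving a conditional gene
    keeps its CSN edge only when the conditional statistic inside each
    conditional gene's box (aggregated by mean or min over conditional
    genes) also exceeds the threshold — an association must be present
    marginally and survive conditioning.  Pairs involving a conditional
    gene keep their unconditional decision.  ``n_conditional = 0``
    reduces exactly to :func:`build_csn`.
    """
    params = params or CsnParams()
    if params.n_conditional == 0:
        return build_csn(expr, k, params)
    if not 0 <= k < expr.n_cells:
        raise IndexError(f"cell index {k} out of range")
    tested = _tested_genes(expr, params)
    cell_id = expr.cell_ids[k]
    if tested.sum() < 2:
        logger.warning("cell %s: fewer than 2 genes pass the expression filter", cell_id)
        return CellNetwork(cell_id, expr.n_genes, np.empty((0, 2), dtype=np.int64))
    z_crit = norm.ppf(1.0 - params.alpha)
    M = _membership(expr, k, params.box_fraction)
    stat = _pair_statistics(M, k, expr.n_cells)
    csn_adj = stat > z_crit
    csn_adj &= np.outer(tested, tested)
    np.fill_diagonal(csn_adj, False)

    csn = CellNetwork.from_adjacency(cell_id, csn_adj)
    cond = select_conditional_genes(csn, params.n_conditional) if params.n_conditional else []
    if not cond:
        return csn

    cond_stats = np.stack([_conditional_statistics(M, k, z) for z in cond])
    agg = cond_stats.mean(axis=0) if params.conditional_agg == "mean" else cond_stats.min(axis=0)

    # pruning semantics: marginal edge must also survive conditioning
    adj = csn_adj & (agg > z_crit)
    # pairs involving a conditional gene keep the unconditional decision
    cond_mask = np.zeros(expr.n_genes, dtype=bool)
    cond_mask[cond] = True
    keep = cond_mask[:, None] | cond_mask[None, :]
    adj = np.where(keep, csn_adj, adj)
    adj &= np.outer(tested, tested)
    np.fill_diagonal(adj, False)
    i, j = np.nonzero(np.triu(adj, k=1))
    return CellNetwork(cell_id, expr.n_genes, np.column_stack([i, j]))


def compute_cndm(expr: ExpressionMatrix, params: CsnParams | None = None) -> DegreeMatrix:
    """Conditional network degree matrix: column k = cell k's CCSN degrees."""
    params = params or CsnParams()
    degrees = np.zeros((expr.n_genes, expr.n_cells), dtype=np.int64)
    for k in range(expr.n_cells):
        try:
            net = build_ccsn(expr, k, params)
        except Exception as exc:  # re-raise with the offending cell named
            raise RuntimeError(f"network construction failed for cell {expr.cell_ids[k]}") from exc
        degrees[:, k] = net.degrees()
    return DegreeMatrix(degrees, list(expr.gene_ids), list(expr.cell_ids))


def aggregate_networks(
    networks: Sequence[CellNetwork],
    gene_ids: Sequence[str],
    min_support: float = 0.05,
) -> nx.Graph:
    """Integrate per-cell networks of one cell type into a weighted graph.

    Edge weight = fraction of input cells whose network contains the
    edge; edges below ``min_support`` are dropped, and only genes with at
    least one retained edge appear as nodes.
    """
    if not networks:
        raise ValidationError("no networks to aggregate")
    n_genes = networks[0].n_genes
    if len(gene_ids) != n_genes:
        raise ValidationError("gene_ids length does not match network gene universe")
    for net in networks:
        if net.n_genes != n_genes:
            raise ValidationError("networks have inconsistent gene universes")
    counts: dict[tuple[int, int], int] = {}
    for net in networks:
        for i, j in net.edges:
            key = (int(i), int(j))
            counts[key] = counts.get(key, 0) + 1
    graph = nx.Graph()
    n_cells = len(networks)
    for (i, j), c in sorted(counts.items()):
        w = c / n_cells
        if w >= min_support:
            graph.add_edge(gene_ids[i], gene_ids[j], weight=w)
    return graph
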