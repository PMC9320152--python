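"""Ligand-receptor communication scoring between cell clusters.

For an ordered (source, target) cluster pair, a ligand-receptor pair is
scored by the mean of the ligand's average expression in the source
cluster and the receptor's average expression in the target cluster.
Significance comes from a label-permutation test: cluster tags of all
cells are reshuffled B times (default 1000) and the p value is the
fraction of permuted scores at least as large as the observed one, so an
observed score in the top 5% of the permutation distribution gets
p = 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CellAnnotation, ExpressionMatrix, ValidationError

__all__ = [
    "LRPair",
    "InteractionResult",
    "read_lr_pairs",
    "expression_summary",
    "interaction_score",
    "pvalue_from_permutations",
    "permutation_pvalue",
    "communication_table",
]

logger = logging.getLogger(__name__)

#: sentinel score for pairs below the expressing-fraction cutoff
NOT_TESTED = float("nan")


@dataclass(frozen=True)
class LRPair:
    pair_id: str
    ligand: str
    receptor: str


@dataclass
class InteractionResult:
    pair_id: str
    source: str
    target: str
    mean_score: float
    p_value: float
    frac_ligand: float
    frac_receptor: float


def read_lr_pairs(path) -> list[LRPair]:
    """Read a ligand-receptor pair table (TSV: pair_id, ligand, receptor)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pair_id", "ligand", "receptor"}
    if not required.issubset(df.columns):
        raise ValidationError(f"LR pair file must have columns {sorted(required)}")
    return [LRPair(r.pair_id, r.ligand, r.receptor) for r in df.itertuples()]


def _cluster_columns(expr: ExpressionMatrix, annotation: CellAnnotation, cluster: str) -> np.ndarray:
    cells = annotation.cells_of(cell_type=cluster)
    if not cells:
        raise ValidationError(f"unknown or empty cluster {cluster!r}")
    pos = {c: i for i, c in enumerate(expr.cell_ids)}
    return np.array([pos[c] for c in cells if c in pos], dtype=int)


def expression_summary(
    expr: ExpressionMatrix, annotation: CellAnnotation, cluster: str, gene: str
) -> tuple[float, float]:
    """(mean expression, expressing fraction) of a gene in one cluster."""
    cols = _cluster_columns(expr, annotation, cluster)
    row = expr.values[expr.gene_index(gene), cols]
    return float(row.mean()), float((row > 0).mean())


def interaction_score(
    expr: ExpressionMatrix,
    annotation: CellAnnotation,
    pair: LRPair,
    source: str,
    target: str,
    min_frac: float = 0.1,
) -> float:
    """Observed interaction score; NaN when either side is under-expressed.

    Score = (ligand mean in source + receptor mean in target) / 2.
    Autocrine signaling (source == target) is allowed.
    """
    try:
        lig_mean, lig_frac = expression_summary(expr, annotation, source, pair.ligand)
        rec_mean, rec_frac = expression_summary(expr, annotation, target, pair.receptor)
    except KeyError as exc:
        logger.info("pair %s skipped: %s", pair.pair_id, exc)
        return NOT_TESTED
    if lig_frac < min_frac or rec_frac < min_frac:
        return NOT_TESTED
    return (lig_mean + rec_mean) / 2.0


def pvalue_from_permutations(observed: float, permuted_scores: np.ndarray) -> float:
    """Permutation p value: fraction of permuted scores >= the observed one.

    No +1 correction, so an observed score larger than every permuted
    score yields p = 0 and one sitting exactly at the top 5% boundary of
    B permutations yields p = 0.05.
    """
    permuted_scores = np.asarray(permuted_scores, dtype=float)
    if permuted_scores.size == 0:
        raise ValidationError("need at least one permuted score")
    return float((permuted_scores >= observed).sum() / permuted_scores.size)


def _permuted_scores(
    lig_row: np.ndarray,
    rec_row: np.ndarray,
    labels: np.ndarray,
    source: str,
    target: str,
    B: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n = labels.size
    out = np.empty(B)
    src_mask = labels == source
    tgt_mask = labels == target
    n_src, n_tgt = int(src_mask.sum()), int(tgt_mask.sum())
    for b in range(B):
        perm = rng.permutation(n)
        ps = perm[src_mask]
        pt = perm[tgt_mask]
        out[b] = (lig_row[ps].sum() / n_src + rec_row[pt].sum() / n_tgt) / 2.0
    return out


def permutation_pvalue(
    expr: ExpressionMatrix,
    annotation: CellAnnotation,
    pair: LRPair,
    source: str,
    target: str,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    min_frac: float = 0.0,
) -> float:
    """Label-permutation p value: fraction of permuted scores >= observed.

    p lies on the grid {0, 1/B, ..., 1}; identical seeds reproduce the
    permutation stream exactly.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    labels = np.asarray(annotation.label_of("cell_type", expr.cell_ids))
    if np.unique(labels).size < 2:
        raise ValidationError("permutation test needs at least 2 clusters")
    observed = interaction_score(expr, annotation, pair, source, target, min_frac=min_frac)
    if math.isnan(observed):
        return NOT_TESTED
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lig_row = expr.values[expr.gene_index(pair.ligand)]
    rec_row = expr.values[expr.gene_index(pair.receptor)]
    perm = _permuted_scores(lig_row, rec_row, labels, source, target, B, rng)
    return pvalue_from_permutations(observed, perm)


def communication_table(
    expr: ExpressionMatrix,
    annotation: CellAnnotation,
    pairs: list[LRPair],
    clusters: list[str] | None = None,
    B: int = 1000,
    seed: int = 0,
    min_frac: float = 0.1,
    include_autocrine: bool = False,
) -> pd.DataFrame:
    """Score every LR pair across every ordered cluster pair.

    Returns a DataFrame sorted by p value then descending score with
    columns (pair, source, target, score, p, neg_log10_p, frac_ligand,
    frac_receptor); ``neg_log10_p`` floors p at 1/B.  Pairs whose genes
    are absent from the matrix are skipped with a log entry; pairs below
    the expressing-fraction cutoff appear with NaN score and p.
    """
    clusters = clusters if clusters is not None else annotation.cell_types
    if len(clusters) < 2 and not include_autocrine:
        raise ValidationError("need at least 2 clusters")
    rng = np.random.default_rng(seed)
    gene_set = set(expr.gene_ids)
    rows = []
    for pair in pairs:
        if pair.ligand not in gene_set or pair.receptor not in gene_set:
            logger.info("pair %s skipped: gene not in matrix", pair.pair_id)
            continue
        for source in clusters:
            for target in clusters:
                if source == target and not include_autocrine:
                    continue
                lig_mean, lig_frac = expression_summary(expr, annotation, source, pair.ligand)
                rec_mean, rec_frac = expression_summary(expr, annotation, target, pair.receptor)
                if lig_frac < min_frac or rec_frac < min_frac:
                    score, p = NOT_TESTED, NOT_TESTED
                else:
                    score = (lig_mean + rec_mean) / 2.0
                    p = permutation_pvalue(
                        expr, annotation, pair, source, target, B=B, seed=rng, min_frac=0.0
                    )
                rows.append(
                    {
                        "pair": pair.pair_id,
                        "source": source,
                        "target": target,
                        "score": score,
                        "p": p,
                        "neg_log10_p": -math.log10(max(p, 1.0 / B)) if not math.isnan(p) else NOT_TESTED,
                        "frac_ligand": lig_frac,
                        "frac_receptor": rec_frac,
                    }
                )
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(
            ["p", "score"], ascending=[True, False], na_position="last"
        ).reset_index(drop=True)
    return table
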