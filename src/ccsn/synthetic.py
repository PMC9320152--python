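"""Synthetic single-cell expression, annotation and survival generators.

The generator emulates the statistical shape of a log(1+x)-normalized
islet single-cell matrix: nonnegative values with a high zero fraction,
two conditions (reference and disease) times several cell types, and
planted structure for every downstream stage —

* co-expression modules: genes coupled through a shared latent factor
  (Gaussian copula with correlation rho), active only in the declared
  conditions;
* dark genes: genes whose module membership switches between conditions
  while their marginal distribution is exactly matched, so they carry a
  network-degree signal but no expression signal;
* ligand-receptor pairs: a ligand upshifted in a source cell type and a
  receptor upshifted in a target cell type;
* survival tables with exponential event times whose hazard depends on
  a median split of a per-sample score.

Marginals are zero-inflated log-normal on the log(1+x) scale: a latent
standard normal is pushed through the probability integral transform, a
``zero_fraction`` lower tail maps to zero and the rest to a log-normal
quantile.  Because the copula only reshapes the joint distribution, the
marginal of every gene is identical in every condition by construction —
the property the dark-gene screen relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import CellAnnotation, ExpressionMatrix, ValidationError

__all__ = [
    "GeneModule",
    "PlantedLRPair",
    "SyntheticSpec",
    "generate_expression",
    "generate_survival",
    "default_dark_spec",
    "default_communication_spec",
]

#: log-normal scale parameter of nonzero values (log(1+x)-scale spread)
SIGMA = 0.6
#: range of per-gene log-normal location parameters
MU_RANGE = (0.7, 2.0)


@dataclass(frozen=True)
class GeneModule:
    """A co-expression module: gene indices, latent correlation, active conditions."""

    genes: tuple[int, ...]
    rho: float
    active_in: tuple[str, ...]


@dataclass(frozen=True)
class PlantedLRPair:
    """A planted ligand-receptor interaction between two cell types."""

    ligand: int
    receptor: int
    source_type: str
    target_type: str
    effect: float = 2.0


@dataclass
class SyntheticSpec:
    """Full description of one synthetic dataset; identical spec + seed
    reproduce the dataset exactly."""

    n_genes: int = 500
    cell_types: tuple[str, ...] = ("beta",)
    conditions: tuple[str, str] = ("ND", "T2D")
    n_cells_per_group: int = 200
    modules: tuple[GeneModule, ...] = ()
    dark_genes: tuple[int, ...] = ()
    zero_fraction: float = 0.3
    lr_pairs: tuple[PlantedLRPair, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if self.n_cells_per_group < 1:
            raise ValidationError("n_cells_per_group must be positive")
        if len(self.conditions) != 2:
            raise ValidationError("conditions must have exactly 2 labels")
        if not 0.0 <= self.zero_fraction < 1.0:
            raise ValidationError("zero_fraction must lie in [0, 1)")
        for mod in self.modules:
            if not 0.0 <= mod.rho < 1.0:
                raise ValidationError("module rho must lie in [0, 1)")
            for g in mod.genes:
                if not 0 <= g < self.n_genes:
                    raise ValidationError(f"module gene index {g} out of range")
            unknown = set(mod.active_in) - set(self.conditions)
            if unknown:
                raise ValidationError(f"module active_in has unknown conditions {unknown}")
        for g in self.dark_genes:
            if not 0 <= g < self.n_genes:
                raise ValidationError(f"dark gene index {g} out of range")
        dark = set(self.dark_genes)
        for i, a in enumerate(self.modules):
            for b in self.modules[i + 1:]:
                shared = set(a.genes) & set(b.genes)
                if shared - dark:
                    raise ValidationError(
                        f"modules overlap outside declared dark genes: {sorted(shared - dark)}"
                    )
        for lr in self.lr_pairs:
            for g in (lr.ligand, lr.receptor):
                if not 0 <= g < self.n_genes:
                    raise ValidationError(f"lr_pairs gene index {g} out of range")
            for t in (lr.source_type, lr.target_type):
                if t not in self.cell_types:
                    raise ValidationError(f"lr_pairs cell type {t!r} not in cell_types")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


def _marginal(u: np.ndarray, mu: np.ndarray, zero_fraction: float) -> np.ndarray:
    """Inverse CDF of the zero-inflated log-normal marginal, vectorized.

    ``u`` is uniform(0,1) of shape (genes, cells); ``mu`` per-gene.
    """
    pi = zero_fraction
    out = np.zeros_like(u)
    nz = u >= pi
    if pi < 1.0:
        # rescale the upper tail to (0,1) and map through the log-normal quantile
        tail = np.clip((u - pi) / (1.0 - pi), 1e-12, 1.0 - 1e-12)
        vals = np.exp(mu[:, None] + SIGMA * norm.ppf(tail))
        out[nz] = vals[nz]
    return out


def generate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, CellAnnotation]:
    """Generate the expression matrix and cell annotation for a spec.

    Cells are laid out group by group in (cell type, condition) order.
    Within a group, genes of every module active in that condition share
    a per-cell latent factor with loading sqrt(rho); all other genes are
    independent.  Planted ligand/receptor genes get a location shift in
    their source/target cell type (both conditions equally).
    """
    ss = np.random.SeedSequence(spec.seed)
    n_groups = len(spec.cell_types) * len(spec.conditions)
    streams = ss.spawn(1 + n_groups)
    rng_params = np.random.default_rng(streams[0])

    mu = rng_params.uniform(*MU_RANGE, size=spec.n_genes)
    # per-cell-type location shifts for planted LR genes
    shifts: dict[str, np.ndarray] = {t: np.zeros(spec.n_genes) for t in spec.cell_types}
    for lr in spec.lr_pairs:
        shifts[lr.source_type][lr.ligand] += lr.effect
        shifts[lr.target_type][lr.receptor] += lr.effect

    blocks: list[np.ndarray] = []
    ann_rows: list[dict] = []
    g_idx = 1
    for ctype in spec.cell_types:
        for cond in spec.conditions:
            rng = np.random.default_rng(streams[g_idx])
            g_idx += 1
            n = spec.n_cells_per_group
            Z = rng.standard_normal((spec.n_genes, n))
            for mod in spec.modules:
                if cond not in mod.active_in:
                    continue
                factor = rng.standard_normal(n)
                idx = np.array(mod.genes)
                Z[idx] = np.sqrt(mod.rho) * factor[None, :] + np.sqrt(1.0 - mod.rho) * Z[idx]
            U = norm.cdf(Z)
            X = _marginal(U, mu + shifts[ctype], spec.zero_fraction)
            blocks.append(X)
            for i in range(n):
                ann_rows.append(
                    {"cell_id": f"{ctype}_{cond}_{i:04d}", "cell_type": ctype, "condition": cond}
                )
    values = np.concatenate(blocks, axis=1)
    annotation = CellAnnotation(pd.DataFrame(ann_rows))
    expr = ExpressionMatrix(values, spec.gene_ids, annotation.cell_ids)
    return expr, annotation


def generate_survival(
    n: int,
    hazard_ratio: float,
    censor_rate: float = 0.0,
    seed: int = 0,
    baseline_hazard: float = 0.1,
) -> pd.DataFrame:
    """Survival table with a score-dependent exponential hazard.

    Scores are standard normal; samples above the score median have
    their event hazard multiplied by ``hazard_ratio``.  Censoring is
    independent exponential with per-sample rate chosen so each sample
    is censored with probability ``censor_rate`` exactly.

    Returns a DataFrame with columns (sample, time, event, score).
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    if hazard_ratio <= 0:
        raise ValidationError("hazard_ratio must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ValidationError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    score = rng.standard_normal(n)
    high = score > np.median(score)
    hazard = baseline_hazard * np.where(high, hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_hazard = hazard * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / censor_hazard)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame(
        {
            "sample": [f"S{i:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "score": score,
        }
    )


def default_dark_spec(seed: int = 0) -> SyntheticSpec:
    """Dark-gene benchmark: 500 genes, one cell type, 2 x 200 cells.

    Genes 0-9 form a module (rho = 0.8) active only in the disease
    condition, so they switch association structure while keeping their
    marginals — the planted dark genes.  The remaining 490 genes are
    null.
    """
    dark = tuple(range(10))
    return SyntheticSpec(
        n_genes=500,
        cell_types=("beta",),
        conditions=("ND", "T2D"),
        n_cells_per_group=200,
        modules=(GeneModule(genes=dark, rho=0.8, active_in=("T2D",)),),
        dark_genes=dark,
        zero_fraction=0.3,
        seed=seed,
    )


def default_communication_spec(seed: int = 0) -> SyntheticSpec:
    """Cell-communication benchmark: two endocrine cell types with one
    planted ligand-receptor pair from alpha to beta."""
    return SyntheticSpec(
        n_genes=120,
        cell_types=("alpha", "beta"),
        conditions=("ND", "T2D"),
        n_cells_per_group=60,
        lr_pairs=(PlantedLRPair(ligand=0, receptor=1, source_type="alpha",
                                target_type="beta", effect=2.0),),
        zero_fraction=0.3,
        seed=seed,
    )
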