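"""End-to-end pipeline: networks, hubs, communication, dark genes, prognosis.

``run_pipeline`` reproduces the full workflow on any input dataset: per
cell type it computes the conditional network degree matrix, integrates
per-cell networks, ranks hubs, scores ligand-receptor communication
across the requested clusters, runs the expression/degree differential
tables and the dark-gene screen, and (optionally) gene-set enrichment
and median-split prognosis.  A manifest records every parameter, the
seed and output checksums so reruns are auditable and byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as ccsn_io
from .communication import communication_table, read_lr_pairs
from .containers import CsnParams, ValidationError
from .differential import differential_table, find_dark_genes, hypergeom_enrichment, read_gmt
from .hubs import mcc_scores, top_hubs
from .network import aggregate_networks, build_ccsn, compute_cndm
from .survival import classify_direction

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration of one pipeline run (loadable from YAML)."""

    expression_path: str
    annotation_path: str
    out_dir: str
    normalize_log1p: bool = False
    csn: CsnParams = field(default_factory=CsnParams)
    cell_types: list[str] | None = None          # None = all annotated types
    conditions: tuple[str, str] | None = None    # (reference, disease)
    min_support: float = 0.05
    top_k_hubs: int = 20
    pairs_path: str | None = None
    comm_clusters: list[str] | None = None
    comm_B: int = 1000
    comm_min_frac: float = 0.1
    dark_p_expr: float = 0.05
    dark_fdr_degree: float = 0.05
    gmt_path: str | None = None
    survival_path: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "csn" in raw and isinstance(raw["csn"], dict):
            raw["csn"] = CsnParams(**raw["csn"])
        if "conditions" in raw and raw["conditions"] is not None:
            raw["conditions"] = tuple(raw["conditions"])
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("expression_path", "annotation_path", "pairs_path", "gmt_path",
                     "survival_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{attr}: file not found: {p}")
        for attr in ("dark_p_expr", "dark_fdr_degree", "min_support"):
            v = getattr(self, attr)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{attr} must lie in (0, 1)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every configured stage; returns the output directory.

    Stages without their optional input (LR pairs, gene sets, survival)
    are skipped with a log entry.  Any stage failure aborts the run with
    the stage name in the exception message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    written: list[Path] = []

    def _stage(name: str):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def _done(name: str) -> None:
        timings[name] = time.perf_counter() - timings[name]

    stage = _stage("read")
    try:
        expr = ccsn_io.read_expression(config.expression_path,
                                       normalize_log1p=config.normalize_log1p)
        annotation = ccsn_io.read_annotation(config.annotation_path)
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    _done(stage)

    cell_types = config.cell_types or annotation.cell_types
    conditions = config.conditions
    dark_reports: list[pd.DataFrame] = []
    all_dark_genes: list[str] = []

    for ctype in cell_types:
        tdir = out / ctype
        tdir.mkdir(exist_ok=True)
        cells = annotation.cells_of(cell_type=ctype)
        if len(cells) < 2:
            logger.warning("cell type %s has %d cells; skipped", ctype, len(cells))
            continue
        sub = expr.subset_cells(cells)

        stage = _stage(f"cndm[{ctype}]")
        try:
            cndm = compute_cndm(sub, config.csn)
            ccsn_io.write_degree_matrix(cndm, tdir / "cndm.tsv")
            written.append(tdir / "cndm.tsv")
            networks = [build_ccsn(sub, k, config.csn) for k in range(sub.n_cells)]
            graph = aggregate_networks(networks, sub.gene_ids, config.min_support)
            ccsn_io.write_network(graph, tdir / "network.tsv")
            written.append(tdir / "network.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        _done(stage)

        stage = _stage(f"hubs[{ctype}]")
        try:
            ranking = top_hubs(mcc_scores(graph), k=config.top_k_hubs)
            pd.DataFrame(ranking.entries, columns=["rank", "gene", "mcc"]).to_csv(
                tdir / "hubs.tsv", sep="\t", index=False
            )
            written.append(tdir / "hubs.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        _done(stage)

        conds = list(conditions) if conditions else annotation.conditions
        have_both = all(
            len(annotation.cells_of(cell_type=ctype, condition=c)) >= 2 for c in conds
        )
        if len(conds) == 2 and have_both:
            stage = _stage(f"dark[{ctype}]")
            try:
                expr_diff = differential_table(sub, annotation, "expression", ctype,
                                               conditions=tuple(conds))
                deg_diff = differential_table(cndm, annotation, "degree", ctype,
                                              conditions=tuple(conds))
                expr_diff.to_csv(tdir / "diff_expression.tsv", sep="\t", index=False,
                                 float_format="%.6g")
                deg_diff.to_csv(tdir / "diff_degree.tsv", sep="\t", index=False,
                                float_format="%.6g")
                written += [tdir / "diff_expression.tsv", tdir / "diff_degree.tsv"]
                dark = find_dark_genes(expr_diff, deg_diff, cell_type=ctype,
                                       p_expr=config.dark_p_expr,
                                       fdr_degree=config.dark_fdr_degree)
                report = pd.DataFrame(
                    [dataclasses.asdict(d) for d in dark],
                    columns=["gene", "cell_type", "expression_p", "degree_fdr", "direction"],
                )
                report.to_csv(tdir / "dark_genes.tsv", sep="\t", index=False,
                              float_format="%.6g")
                written.append(tdir / "dark_genes.tsv")
                dark_reports.append(report)
                all_dark_genes += [d.gene for d in dark]
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
            _done(stage)
        else:
            logger.info("cell type %s lacks both conditions; differential stage skipped", ctype)

    if config.pairs_path:
        stage = _stage("communication")
        try:
            pairs = read_lr_pairs(config.pairs_path)
            table = communication_table(
                expr, annotation, pairs,
                clusters=config.comm_clusters, B=config.comm_B,
                seed=config.seed, min_frac=config.comm_min_frac,
            )
            table.to_csv(out / "communication.tsv", sep="\t", index=False,
                         float_format="%.6g")
            written.append(out / "communication.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        _done(stage)
    else:
        logger.info("no LR pairs file; communication stage skipped")

    if config.gmt_path and all_dark_genes:
        stage = _stage("enrichment")
        try:
            collection = read_gmt(config.gmt_path)
            enr = hypergeom_enrichment(sorted(set(all_dark_genes)), collection, expr.gene_ids)
            enr.to_csv(out / "dark_enrichment.tsv", sep="\t", index=False,
                       float_format="%.6g")
            written.append(out / "dark_enrichment.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        _done(stage)

    if config.survival_path:
        stage = _stage("survival")
        try:
            surv = ccsn_io.read_survival(config.survival_path)
            call = classify_direction(surv)
            pd.DataFrame(
                [{"logrank_p": call.logrank_p, "direction": call.direction}]
            ).to_csv(out / "prognosis.tsv", sep="\t", index=False, float_format="%.6g")
            written.append(out / "prognosis.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        _done(stage)

    manifest = {
        "seed": config.seed,
        "parameters": {
            **dataclasses.asdict(config.csn),
            "min_support": config.min_support,
            "top_k_hubs": config.top_k_hubs,
            "comm_B": config.comm_B,
            "comm_min_frac": config.comm_min_frac,
            "dark_p_expr": config.dark_p_expr,
            "dark_fdr_degree": config.dark_fdr_degree,
            "normalize_log1p": config.normalize_log1p,
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
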