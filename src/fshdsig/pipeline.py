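"""End-to-end orchestration: simulate/load -> normalize -> score -> evaluate.

:func:`run_pipeline` turns a :class:`PipelineConfig` into a JSON analysis
report plus TSV mirrors (size factors, score table, correlation matrices).
The report is a pure function of (inputs, config, seed): all randomness is
seeded, orderings are deterministic, and repeated runs produce byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import evaluate_predictors
from .io import (
    SignatureGeneSets,
    ValidationError,
    metadata_frame,
    read_counts,
    read_gene_sets,
    read_metadata,
)
from .normalization import compute_size_factors
from .scoring import ScoreConfig, compute_signature_scores, correct_for_fat
from .simulate import CohortConfig, generate_cohort, signature_gene_sets, write_fixtures
from .stats import cohort_summary, correlation_matrix, encode_for_correlation, roc_auc

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("fshdsig")

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Inputs and switches for one pipeline run.

    Exactly one of ``counts_path`` (with ``metadata_path``/``gene_sets_path``)
    or ``simulation`` must be given.
    """

    counts_path: str | None = None
    metadata_path: str | None = None
    gene_sets_path: str | None = None
    simulation: CohortConfig | None = None
    out_dir: str = "fshdsig_out"
    seed: int = 0
    dux4_threshold: float = 20.0
    fat_threshold: float = 15.0
    pax7_k: int = 10
    fat_correct: bool = False
    exclude_replicates: bool = False
    restrict_qn_to_targets: bool = False

    def __post_init__(self) -> None:
        has_files = self.counts_path is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValidationError("provide exactly one of input paths or a simulation config")
        if has_files and (self.metadata_path is None or self.gene_sets_path is None):
            raise ValidationError("file input requires counts, metadata and gene-set paths")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.time()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle to cfg.out_dir.

    Returns the report dict.  Stages: input (load or simulate), size factors,
    signature scoring, biomarker evaluation, ROC, correlation matrix, cohort
    summary, report writing.  Any stage failure is re-raised with the stage
    name attached.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        t0 = _stage(stage)
        if cfg.simulation is not None:
            sim_cfg = cfg.simulation
            counts, records, gt = generate_cohort(sim_cfg)
            gene_sets = signature_gene_sets(sim_cfg)
            write_fixtures(counts, records, gene_sets, gt, out / "fixtures")
        else:
            counts = read_counts(cfg.counts_path)
            records = read_metadata(cfg.metadata_path)
            gene_sets = read_gene_sets(cfg.gene_sets_path)
        meta = metadata_frame(records)
        missing = [b for b in counts.sample_ids if b not in meta.index]
        if missing:
            raise ValidationError(f"samples without metadata: {missing}")

        stage = "size_factors"
        _stage(stage)
        sf = compute_size_factors(counts)
        sf.factors.to_csv(out / "size_factors.tsv", sep="\t", header=True)

        stage = "scoring"
        _stage(stage)
        score_cfg = ScoreConfig(
            dux4_threshold=cfg.dux4_threshold,
            pax7_k=cfg.pax7_k,
            fat_correction=cfg.fat_correct,
            restrict_qn_to_targets=cfg.restrict_qn_to_targets,
        )
        fshd_ids = meta.index[meta["group"] == "FSHD"]
        scores = compute_signature_scores(
            counts, gene_sets, fshd_biopsies=fshd_ids, config=score_cfg, size_factors=sf
        )
        if cfg.fat_correct:
            fat = pd.to_numeric(meta["fat_fraction"], errors="coerce").reindex(scores.index)
            scores["dux4_score_fat_corrected"] = correct_for_fat(scores["dux4_score"], fat)
        scores.to_csv(out / "scores.tsv", sep="\t", na_rep="NA")

        stage = "biomarker_evaluation"
        _stage(stage)
        biomarker = evaluate_predictors(
            meta,
            scores["dux4_class"],
            fat_threshold=cfg.fat_threshold,
            exclude_replicates=cfg.exclude_replicates,
        )

        stage = "roc"
        _stage(stage)
        group_binary = (meta["group"] == "FSHD").astype(int).reindex(scores.index)
        roc = {}
        for score_col in ("dux4_log", "pax7_score"):
            res = roc_auc(scores[score_col].to_numpy(), group_binary.to_numpy())
            roc[score_col] = {
                "auc": res.auc,
                "fpr": res.fpr,
                "tpr": res.tpr,
                "thresholds": res.thresholds,
            }

        stage = "correlation_matrix"
        _stage(stage)
        encoded = encode_for_correlation(meta, scores[["dux4_log", "pax7_score", "marker_content_index"]])
        corr = correlation_matrix(encoded)
        corr.pearson_r.to_csv(out / "correlation_pearson_r.tsv", sep="\t", na_rep="NA")
        corr.spearman_rho.to_csv(out / "correlation_spearman_rho.tsv", sep="\t", na_rep="NA")

        stage = "cohort_summary"
        _stage(stage)
        summary = [r.as_dict() for r in cohort_summary(meta, scores[["dux4_log", "pax7_score"]])]

        stage = "report"
        _stage(stage)
        report = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "package_version": __version__,
            "seed": cfg.seed if cfg.simulation is None else cfg.simulation.seed,
            "config": {
                "dux4_threshold": cfg.dux4_threshold,
                "fat_threshold": cfg.fat_threshold,
                "pax7_k": cfg.pax7_k,
                "fat_correct": cfg.fat_correct,
                "exclude_replicates": cfg.exclude_replicates,
                "restrict_qn_to_targets": cfg.restrict_qn_to_targets,
            },
            "n_samples": counts.n_samples,
            "n_genes": counts.n_genes,
            "size_factors": {"n_reference_genes": sf.n_reference_genes},
            "dux4_positive": {
                "FSHD": int(((scores["dux4_class"] == "POS") & (meta["group"] == "FSHD")).sum()),
                "CTRL": int(((scores["dux4_class"] == "POS") & (meta["group"] == "CTRL")).sum()),
            },
            "biomarker_evaluation": biomarker,
            "roc": roc,
            "correlation_matrix": {
                "variables": corr.variables,
                "pearson_r": corr.pearson_r.to_numpy(),
                "spearman_rho": corr.spearman_rho.to_numpy(),
                "pearson_p": corr.pearson_p.to_numpy(),
                "spearman_p": corr.spearman_p.to_numpy(),
            },
            "cohort_summary": summary,
        }
        report = _jsonable(report)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, allow_nan=False)
            fh.write("\n")
        logger.info("done in %.1fs", time.time() - t0)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
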