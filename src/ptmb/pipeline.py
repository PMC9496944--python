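"""End-to-end orchestration: cohorts -> enrichment -> selection -> P-TMB -> ROC.

The pipeline is a pure function of its configuration: given the same input
files (or simulation seed) and parameters it writes byte-identical
artifacts.  Stages run in method order — per-cohort mutation-frequency
matrix, GSVA-style enrichment, Mann-Whitney response tests, cross-cohort
PP/NP selection, per-sample TMB/P-TMB, per-cohort ROC/AUC and Youden
cutoffs, global threshold, confusion matrices — and every intermediate
table is persisted.

Selection/evaluation circularity: with ``leave_one_out`` (default) the
pathways scored on a cohort are selected from the *other* cohorts only, so
each cohort's AUC is an out-of-sample estimate; ``leave_one_out=False``
evaluates on the discovery cohorts themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import burden as burden_mod
from . import evaluation, pathway_scoring
from .exceptions import ValidationError
from .io_formats import (
    CohortDataset,
    PathwayCollection,
    read_clinical,
    read_gene_lengths,
    read_gmt,
    read_mutations,
    write_table,
)
from .synthetic_data import SimulationConfig, simulate_cohorts

log = logging.getLogger("ptmb")

__all__ = ["PipelineConfig", "PipelineResult", "run_full_pipeline", "load_pipeline_config"]


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs, parameters, output directory."""

    outdir: str
    cohorts: list[dict] = field(default_factory=list)  # name/mutations/clinical paths
    lengths_path: str | None = None
    gmt_path: str | None = None
    simulate: SimulationConfig | None = None
    dialect: str = "maf_min"
    alpha: float = 0.05
    fc_min: float = 1.5
    min_datasets: int = 4
    denominator_mb: float = 30.0
    kcdf: str = "ecdf"
    es_mode: str = "mx_diff"
    matrix_mode: str = "per_mb"
    threshold: float | None = None  # fixed threshold; None = Youden average
    leave_one_out: bool = True
    seed: int = 0


@dataclass
class PipelineResult:
    selection: pathway_scoring.PathwaySelection
    burden_tables: dict[str, pd.DataFrame]
    auc_ptmb: dict[str, float]
    auc_tmb: dict[str, float]
    cutoffs: dict[str, float]
    global_threshold: float
    confusion: dict[str, pd.DataFrame]
    report_path: Path


def load_pipeline_config(path) -> PipelineConfig:
    """Read a YAML pipeline configuration."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulate", None)
    cfg = PipelineConfig(outdir=raw.pop("outdir", "ptmb_out"), **raw)
    if sim is not None:
        cfg.simulate = SimulationConfig(**sim)
    return cfg


def _load_cohorts(config: PipelineConfig):
    if config.simulate is not None:
        log.info("stage simulate: %s", config.simulate)
        sim = simulate_cohorts(config.simulate)
        return sim.cohorts, sim.lengths, sim.pathways
    if not config.cohorts or not config.lengths_path or not config.gmt_path:
        raise ValidationError(
            "config needs either `simulate` or cohorts + lengths_path + gmt_path"
        )
    cohorts = []
    for spec in config.cohorts:
        cohorts.append(
            CohortDataset(
                name=spec["name"],
                mutations=read_mutations(spec["mutations"], config.dialect),
                clinical=read_clinical(spec["clinical"]),
            )
        )
    return cohorts, read_gene_lengths(config.lengths_path), read_gmt(config.gmt_path)


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and persist artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {
        k: getattr(config, k)
        for k in ("alpha", "fc_min", "min_datasets", "denominator_mb", "kcdf",
                  "es_mode", "matrix_mode", "leave_one_out", "seed")
    }

    cohorts, lengths, pathways = _load_cohorts(config)
    names = [c.name for c in cohorts]
    if len(cohorts) < config.min_datasets:
        raise ValidationError(
            f"{len(cohorts)} cohorts < min_datasets={config.min_datasets}"
        )
    if config.leave_one_out and len(cohorts) - 1 < config.min_datasets:
        raise ValidationError(
            "leave_one_out needs at least min_datasets + 1 cohorts"
        )

    log.info("stage enrichment: %d cohorts, params %s", len(cohorts), params)
    tests_by_cohort: dict[str, pd.DataFrame] = {}
    for cohort in cohorts:
        M = pathway_scoring.build_mutation_frequency_matrix(
            cohort, lengths=lengths, mode=config.matrix_mode
        )
        E = pathway_scoring.gsva_scores(
            M, pathways, kcdf=config.kcdf, es_mode=config.es_mode, seed=config.seed
        )
        tests = pathway_scoring.test_pathway_response(E, cohort.response_series())
        tests_by_cohort[cohort.name] = tests
        write_table(E.reset_index(names="pathway"), outdir / f"es_{cohort.name}.tsv", params)
        write_table(tests, outdir / f"tests_{cohort.name}.tsv", params)

    log.info("stage selection: min_datasets=%d", config.min_datasets)
    selection = pathway_scoring.select_pathways(
        tests_by_cohort, pathways, alpha=config.alpha, min_datasets=config.min_datasets
    )
    write_table(selection.table, outdir / "selection.tsv", params)
    (outdir / "pp_genes.txt").write_text(
        "".join(g + "\n" for g in sorted(selection.pp_genes)), encoding="utf-8"
    )
    (outdir / "np_genes.txt").write_text(
        "".join(g + "\n" for g in sorted(selection.np_genes)), encoding="utf-8"
    )

    log.info("stage burden/evaluation (leave_one_out=%s)", config.leave_one_out)
    burden_tables: dict[str, pd.DataFrame] = {}
    auc_ptmb: dict[str, float] = {}
    auc_tmb: dict[str, float] = {}
    cutoffs: dict[str, float] = {}
    selections_for: dict[str, pathway_scoring.PathwaySelection] = {}
    for cohort in cohorts:
        if config.leave_one_out:
            held_in = {k: v for k, v in tests_by_cohort.items() if k != cohort.name}
            sel = pathway_scoring.select_pathways(
                held_in, pathways, alpha=config.alpha, min_datasets=config.min_datasets
            )
        else:
            sel = selection
        selections_for[cohort.name] = sel
        if not sel.pp_genes:
            log.warning("cohort %s: empty PP selection; P-TMB PP term is zero",
                        cohort.name)
        if not sel.np_genes:
            log.warning("cohort %s: empty NP selection; P-TMB NP term is zero",
                        cohort.name)
        table = burden_mod.compute_burden_table(
            cohort, sel.pp_genes, sel.np_genes, lengths,
            denominator_mb=config.denominator_mb,
            allow_empty_np=True, allow_empty_pp=True,
        )
        labels = (cohort.response_series() == "R").astype(int).to_numpy()
        burden_tables[cohort.name] = table
        write_table(table, outdir / f"burden_{cohort.name}.tsv", params)
        auc_ptmb[cohort.name] = evaluation.roc_curve(table["ptmb"], labels).auc
        auc_tmb[cohort.name] = evaluation.roc_curve(table["tmb"], labels).auc
        cutoffs[cohort.name] = evaluation.youden_cutpoint(table["ptmb"], labels).cutoff

    threshold = (
        config.threshold
        if config.threshold is not None
        else evaluation.global_threshold(list(cutoffs.values()))
    )
    confusion: dict[str, pd.DataFrame] = {}
    for cohort in cohorts:
        labels = (cohort.response_series() == "R").astype(int).to_numpy()
        _, conf = evaluation.classify_by_threshold(
            burden_tables[cohort.name]["ptmb"], threshold, labels
        )
        confusion[cohort.name] = conf

    report = pd.DataFrame(
        {
            "cohort": names,
            "auc_ptmb": [auc_ptmb[n] for n in names],
            "auc_tmb": [auc_tmb[n] for n in names],
            "youden_cutoff": [cutoffs[n] for n in names],
            "tp": [int(confusion[n]["tp"].iloc[0]) for n in names],
            "fp": [int(confusion[n]["fp"].iloc[0]) for n in names],
            "tn": [int(confusion[n]["tn"].iloc[0]) for n in names],
            "fn": [int(confusion[n]["fn"].iloc[0]) for n in names],
        }
    )
    write_table(report, outdir / "report.tsv", params)
    report_path = outdir / "report.txt"
    with open(report_path, "w", encoding="utf-8") as fh:
        fh.write("P-TMB pipeline report\n")
        fh.write("=====================\n")
        for k, v in params.items():
            fh.write(f"{k}: {v}\n")
        fh.write(f"cohorts: {', '.join(names)}\n")
        fh.write(f"positive pathways (PP): {', '.join(selection.pp_pathways) or '-'}\n")
        fh.write(f"negative pathways (NP): {', '.join(selection.np_pathways) or '-'}\n")
        fh.write(f"PP genes: {len(selection.pp_genes)}  NP genes: {len(selection.np_genes)}\n")
        fh.write(f"global P-TMB threshold: {threshold:.6g}\n")
        for n in names:
            conf = confusion[n]
            fh.write(
                f"{n}: AUC(P-TMB)={auc_ptmb[n]:.4f} AUC(TMB)={auc_tmb[n]:.4f} "
                f"cutoff={cutoffs[n]:.6g} "
                f"tp={int(conf['tp'].iloc[0])} fp={int(conf['fp'].iloc[0])} "
                f"tn={int(conf['tn'].iloc[0])} fn={int(conf['fn'].iloc[0])}\n"
            )
    log.info("pipeline finished; report at %s", report_path)
    return PipelineResult(
        selection=selection,
        burden_tables=burden_tables,
        auc_ptmb=auc_ptmb,
        auc_tmb=auc_tmb,
        cutoffs=cutoffs,
        global_threshold=threshold,
        confusion=confusion,
        report_path=report_path,
    )
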