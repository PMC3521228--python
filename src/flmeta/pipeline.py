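"""End-to-end pipeline: simulate/read → preprocess → score → classify →
propensity → covariates, with a structured config and a run report."""
from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import covariates as cov
from . import flscore, preprocess, propensity
from .dataset import (FLOAT_FORMAT, NA_REP, read_expression_tsv,
                      read_probe_map)
from .errors import PipelineError
from .synthetic import SimulationConfig, simulate_collection, write_collection

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run.

    Either ``input_dir`` points at an existing collection (the file layout
    written by the simulator) or ``simulation`` describes one to generate.
    """

    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    min_arrays: int = preprocess.MIN_ARRAYS_DEFAULT
    collapse: bool = True
    quantile: float = 0.05
    min_datasets: int | None = None
    normalized_ranks: bool = False
    window: int = 2000
    step: int = 50
    n_reps: int = 100
    alpha: float = 0.05
    bin_width: int = 300
    min_bin_count: int = cov.MIN_BIN_COUNT_DEFAULT
    mirna_group_rule: str = "any"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulation is None and self.input_dir is None:
            self.simulation = SimulationConfig(seed=self.seed)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim = data.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


@dataclass
class RunReport:
    """Per-stage record of parameters, counts and the output-file manifest."""

    config: dict
    stages: list[dict] = field(default_factory=list)
    manifest: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def add_stage(self, stage: str, **counts) -> None:
        self.stages.append({"stage": stage, **counts})

    def add_files(self, *paths) -> None:
        self.manifest.extend(str(p) for p in paths)

    def validate_manifest(self) -> None:
        for path in self.manifest:
            p = pathlib.Path(path)
            if not p.exists() or p.stat().st_size == 0:
                raise PipelineError(f"[report] manifest file missing or empty: {path}")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "stages": self.stages,
                       "manifest": self.manifest,
                       "failed_stage": self.failed_stage},
                      fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep=NA_REP,
              index=index)


def _load_input_dir(indir: pathlib.Path):
    datasets = [read_expression_tsv(p, dataset_id=p.stem.removeprefix("expression_"))
                for p in sorted(indir.glob("expression_*.tsv"))]
    if not datasets:
        raise PipelineError(f"[input] no expression_*.tsv files in {indir}")
    pm_path = indir / "probe_map.tsv"
    probe_map = read_probe_map(pm_path) if pm_path.exists() else None
    target_maps = [propensity.TargetMap.read_tsv(p)
                   for p in sorted(indir.glob("targets_*.tsv"))]
    annot_path = indir / "annotations.tsv"
    annotations = cov.read_annotation_tsv(annot_path) if annot_path.exists() else None
    expr_path = indir / "mirna_expression.tsv"
    mirna_expr = (cov.read_mirna_expression_tsv(expr_path)
                  if expr_path.exists() else None)
    return datasets, probe_map, target_maps, annotations, mirna_expr


def run_pipeline(config: PipelineConfig, outdir) -> RunReport:
    """Execute the full analysis; all outputs land under ``outdir``.

    Any stage error aborts the run with a stage-named :class:`PipelineError`;
    the partially written report records the failed stage.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())
    stage = "init"
    try:
        # -- inputs ---------------------------------------------------------
        if config.input_dir is not None:
            stage = "input"
            (datasets, probe_map, target_maps,
             annotations, mirna_expr) = _load_input_dir(pathlib.Path(config.input_dir))
        else:
            stage = "simulate"
            collection = simulate_collection(config.simulation)
            sim_dir = outdir / "simulated"
            report.add_files(*write_collection(collection, sim_dir))
            datasets = collection.datasets
            probe_map = collection.truth.probe_map
            target_maps = [collection.target_map]
            annotations = collection.annotations
            mirna_expr = collection.mirna_expression
        report.add_stage(stage, n_datasets=len(datasets))

        # -- preprocess -----------------------------------------------------
        stage = "preprocess"
        kept = preprocess.filter_datasets(datasets, config.min_arrays)
        processed = [preprocess.preprocess_dataset(ds, probe_map,
                                                   collapse=config.collapse)
                     for ds in kept]
        proc_dir = outdir / "processed"
        proc_dir.mkdir(exist_ok=True)
        for ds in processed:
            path = proc_dir / f"{ds.dataset_id}.tsv"
            _write_tsv(ds.values, path)
            report.add_files(path)
        report.add_stage(stage, n_retained=len(processed),
                         n_excluded=len(datasets) - len(kept),
                         min_arrays=config.min_arrays)

        # -- score ----------------------------------------------------------
        stage = "score"
        matrix, scores = flscore.score_collection(
            processed, min_datasets=config.min_datasets,
            normalized=config.normalized_ranks)
        _write_tsv(matrix, outdir / "ranked_cv_matrix.tsv")
        _write_tsv(scores, outdir / "fl_scores.tsv")
        report.add_files(outdir / "ranked_cv_matrix.tsv", outdir / "fl_scores.tsv")
        report.add_stage(stage, n_genes_scored=len(scores))

        # -- classify -------------------------------------------------------
        stage = "classify"
        classification = flscore.classify_genes(scores, q=config.quantile)
        _write_tsv(classification.to_frame(), outdir / "classification.tsv")
        report.add_files(outdir / "classification.tsv")
        report.add_stage(stage, q=config.quantile,
                         n_se=len(classification.se_genes),
                         n_fl=len(classification.fl_genes))

        # -- propensity -----------------------------------------------------
        stage = "propensity"
        prop_dir = outdir / "propensity"
        prop_dir.mkdir(exist_ok=True)
        enrich_frames = []
        for tm in target_maps:
            enrich_frames.append(propensity.enrichment_test(classification, tm).to_frame())
            control = propensity.random_control(classification, tm,
                                                n_reps=config.n_reps,
                                                seed=config.seed)
            _write_tsv(control.to_frame(),
                       prop_dir / f"random_control_{tm.source}.tsv", index=False)
            comparison = propensity.target_vs_nontarget_fl(scores, tm)
            _write_tsv(comparison.to_frame(),
                       prop_dir / f"group_comparison_{tm.source}.tsv", index=False)
            windows = propensity.sliding_window(scores, tm,
                                                window=config.window,
                                                step=config.step)
            _write_tsv(windows.table,
                       prop_dir / f"window_series_{tm.source}.tsv", index=False)
            mirnas = propensity.classify_mirnas(classification, tm,
                                                alpha=config.alpha)
            _write_tsv(mirnas.table,
                       prop_dir / f"mirna_classification_{tm.source}.tsv",
                       index=False)
            report.add_files(
                prop_dir / f"random_control_{tm.source}.tsv",
                prop_dir / f"group_comparison_{tm.source}.tsv",
                prop_dir / f"window_series_{tm.source}.tsv",
                prop_dir / f"mirna_classification_{tm.source}.tsv")
            report.add_stage(f"propensity:{tm.source}",
                             enrichment_p=enrich_frames[-1]["p_value"].iloc[0],
                             window_r=windows.pearson_r,
                             n_se_mirnas=mirnas.n_se_mirnas,
                             n_fl_mirnas=mirnas.n_fl_mirnas)
        _write_tsv(pd.concat(enrich_frames, ignore_index=True),
                   prop_dir / "enrichment.tsv", index=False)
        report.add_files(prop_dir / "enrichment.tsv")

        # -- covariates -----------------------------------------------------
        stage = "covariates"
        cov_dir = outdir / "covariates"
        cov_dir.mkdir(exist_ok=True)
        tm = target_maps[0] if len(target_maps) == 1 else \
            propensity.TargetMap.union(target_maps)
        counts_series = cov.group_by_mirna_count(scores, tm,
                                                 min_bin_count=config.min_bin_count)
        _write_tsv(counts_series.table, cov_dir / "mirna_count_bins.tsv",
                   index=False)
        report.add_files(cov_dir / "mirna_count_bins.tsv")
        cov_counts: dict = {"mirna_count_r": counts_series.pearson_r}
        if annotations is not None:
            utr_series = cov.bin_by_utr_length(scores, annotations, tm,
                                               bin_width=config.bin_width,
                                               min_bin_count=config.min_bin_count)
            _write_tsv(utr_series.table, cov_dir / "utr_bins.tsv", index=False)
            utr_cmp = cov.compare_utr_length(classification, annotations, tm)
            _write_tsv(utr_cmp.to_frame(), cov_dir / "utr_comparison.tsv",
                       index=False)
            tfbs_series = cov.tfbs_correlation(scores, annotations,
                                               min_bin_count=config.min_bin_count)
            _write_tsv(tfbs_series.table, cov_dir / "tfbs_bins.tsv", index=False)
            report.add_files(cov_dir / "utr_bins.tsv",
                             cov_dir / "utr_comparison.tsv",
                             cov_dir / "tfbs_bins.tsv")
            cov_counts.update(utr_r=utr_series.pearson_r,
                              tfbs_r=tfbs_series.pearson_r)
        if mirna_expr is not None:
            expr_cmp = cov.compare_mirna_expression(classification, tm,
                                                    mirna_expr,
                                                    rule=config.mirna_group_rule)
            _write_tsv(expr_cmp.to_frame(),
                       cov_dir / "mirna_expression_comparison.tsv", index=False)
            report.add_files(cov_dir / "mirna_expression_comparison.tsv")
            cov_counts["mirna_expression_p"] = expr_cmp.p_value
        report.add_stage(stage, **cov_counts)

        stage = "report"
        report.validate_manifest()
        report.write(outdir / "report.json")
        return report
    except PipelineError:
        report.failed_stage = stage
        report.write(outdir / "report.json")
        raise
    except Exception as exc:
        report.failed_stage = stage
        report.write(outdir / "report.json")
        raise PipelineError(f"[{stage}] {exc}") from exc
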