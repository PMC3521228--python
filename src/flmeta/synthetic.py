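"""Synthetic multi-dataset expression collections with planted structure.

The generator emulates the statistical structure of a meta-analysis corpus of
microarray studies: many datasets of heterogeneous size measured on a shared
gene universe, with two planted noise classes ("stable" vs "fluctuant"
genes), several probes per gene, miRNA→target maps with a controllable
enrichment of targets among stable genes, per-gene annotations (3'-UTR
length, promoter TFBS count) stochastically coupled to the planted noise
class, and a miRNA × tissue expression table.

Intensity model
---------------
Each gene g receives one linear-scale baseline ``B_g`` drawn log-normally
(shared across datasets).  In dataset d, sample s the gene-level intensity is

    X_{g,d,s} = B_g * exp(eps),   eps ~ Normal(0, sigma_g)

where ``sigma_g`` is ``sigma_stable`` or ``sigma_fluctuant`` according to the
planted class.  Multiplicative log-normal noise makes the linear-scale CV a
monotone function of sigma (CV = sqrt(exp(sigma^2) - 1)), so the planted
classes are recoverable by the CV-rank statistic downstream.  When
``probes_per_gene > 1``, each probe of a gene reports the gene signal times
independent log-normal probe noise (SD ``probe_sigma``), so probe collapsing
is exercised meaningfully.

All randomness is drawn from ``numpy`` generators seeded deterministically
from ``config.seed`` plus a fixed per-purpose stream code (and the dataset
index for expression), so identical configs give bit-identical output.
"""
from __future__ import annotations

import logging
import math
import numbers
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (ExpressionDataset, LINEAR, write_expression_tsv,
                      write_probe_map)
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

STABLE = "stable"
FLUCTUANT = "fluctuant"

# fixed stream codes so each generator has an independent, reproducible stream
_STREAMS = {"truth": 1, "expression": 2, "targets": 3,
            "annotations": 4, "mirna_expression": 5}


def _rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        [int(seed), _STREAMS[stream], int(index)]))


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study collection.

    Defaults describe the reference simulation used throughout the package:
    20 datasets of 10 arrays over 5,000 genes, 10% fluctuant genes with a
    6-fold noise-SD contrast (0.1 vs 0.6 on the natural-log scale), two
    probes per gene, 50 miRNAs with 200 targets each enriched 3:1 toward
    stable genes, positive UTR/TFBS couplings and a 31-tissue miRNA
    expression table.
    """

    n_genes: int = 5000
    n_datasets: int = 20
    #: one int (shared by all datasets) or a per-dataset list; each > 6
    samples_per_dataset: int | list[int] = 10
    fluctuant_fraction: float = 0.10
    #: natural-log-scale noise SD of stable / fluctuant genes
    sigma_stable: float = 0.1
    sigma_fluctuant: float = 0.6
    #: one int or a per-gene list of probe counts
    probes_per_gene: int | list[int] = 2
    probe_sigma: float = 0.1
    #: natural-log location/scale of the per-gene baseline intensity
    baseline_log_mean: float = 6.5
    baseline_log_sd: float = 1.0
    n_mirnas: int = 50
    targets_per_mirna: int = 200
    #: odds ratio (>= 0) favouring stable genes as targets; 1 = uniform
    target_enrichment_odds: float = 3.0
    #: shift (natural-log units) added to annotation distributions of
    #: fluctuant genes; 0 = independence of annotation and noise class
    utr_coupling: float = 1.0
    tfbs_coupling: float = 1.0
    #: natural-log location/scale of 3'-UTR length (nt)
    utr_log_mean: float = math.log(750.0)
    utr_log_sd: float = 1.0
    #: negative-binomial mean / dispersion of the promoter TFBS count
    tfbs_mean: float = 8.0
    tfbs_dispersion: float = 3.0
    n_tissues: int = 31
    mirna_log_mean: float = 4.0
    mirna_log_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        def _positive_int(name):
            v = getattr(self, name)
            if not isinstance(v, numbers.Integral) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")

        for name in ("n_genes", "n_datasets", "n_mirnas",
                     "targets_per_mirna", "n_tissues"):
            _positive_int(name)
        if not isinstance(self.seed, numbers.Integral) or self.seed < 0:
            raise ConfigurationError(f"seed must be a non-negative integer, got {self.seed!r}")
        if not 0.0 < self.fluctuant_fraction < 1.0:
            raise ConfigurationError(
                f"fluctuant_fraction must lie strictly in (0, 1), got {self.fluctuant_fraction!r}")
        if not self.sigma_stable > 0:
            raise ConfigurationError(f"sigma_stable must be > 0, got {self.sigma_stable!r}")
        if not self.sigma_fluctuant > self.sigma_stable:
            raise ConfigurationError(
                "sigma_fluctuant must be strictly greater than sigma_stable, got "
                f"sigma_fluctuant={self.sigma_fluctuant!r} <= sigma_stable={self.sigma_stable!r}")
        if self.probe_sigma < 0:
            raise ConfigurationError(f"probe_sigma must be >= 0, got {self.probe_sigma!r}")
        if self.target_enrichment_odds < 0:
            raise ConfigurationError(
                f"target_enrichment_odds must be >= 0, got {self.target_enrichment_odds!r}")
        for n in self.samples_list():
            if n <= 6:
                raise ConfigurationError(
                    f"samples_per_dataset entries must each exceed 6 arrays, got {n}")
        ppg = self.probes_list()
        if any(p < 1 for p in ppg):
            raise ConfigurationError("probes_per_gene entries must be >= 1")
        if self.utr_log_sd <= 0 or self.tfbs_dispersion <= 0 or self.tfbs_mean <= 0:
            raise ConfigurationError(
                "utr_log_sd, tfbs_mean and tfbs_dispersion must be positive")

    def samples_list(self) -> list[int]:
        if isinstance(self.samples_per_dataset, numbers.Integral):
            return [int(self.samples_per_dataset)] * self.n_datasets
        lst = [int(v) for v in self.samples_per_dataset]
        if len(lst) != self.n_datasets:
            raise ConfigurationError(
                f"samples_per_dataset has {len(lst)} entries but n_datasets={self.n_datasets}")
        return lst

    def probes_list(self) -> list[int]:
        if isinstance(self.probes_per_gene, numbers.Integral):
            return [int(self.probes_per_gene)] * self.n_genes
        lst = [int(v) for v in self.probes_per_gene]
        if len(lst) != self.n_genes:
            raise ConfigurationError(
                f"probes_per_gene has {len(lst)} entries but n_genes={self.n_genes}")
        return lst


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated collection."""

    gene_class: pd.Series          # gene -> {stable, fluctuant}
    sigma: pd.Series               # gene -> true log-scale noise SD
    probe_map: pd.Series           # probe -> gene
    seed: int
    target_status: dict[str, pd.Series] = field(default_factory=dict)
    planted_odds: dict[str, float] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.gene_class.index)

    @property
    def stable_genes(self) -> list[str]:
        return list(self.gene_class.index[self.gene_class == STABLE])

    @property
    def fluctuant_genes(self) -> list[str]:
        return list(self.gene_class.index[self.gene_class == FLUCTUANT])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-{i + 1:03d}" for i in range(n)]


def generate_expression_datasets(
        config: SimulationConfig) -> tuple[list[ExpressionDataset], SyntheticTruth]:
    """Simulate the expression collection and return it with its truth.

    Returns one linear-scale :class:`ExpressionDataset` per configured
    dataset.  When every gene has a single probe the rows are gene
    identifiers and the probe map is the identity; otherwise rows are
    ``<gene>_p<j>`` probe identifiers.
    """
    config.validate()
    genes = _gene_ids(config.n_genes)
    rng = _rng(config.seed, "truth")

    n_fluct = int(round(config.n_genes * config.fluctuant_fraction))
    n_fluct = min(max(n_fluct, 1), config.n_genes - 1)
    fluct_idx = rng.choice(config.n_genes, size=n_fluct, replace=False)
    classes = np.full(config.n_genes, STABLE, dtype=object)
    classes[fluct_idx] = FLUCTUANT
    sigma = np.where(classes == FLUCTUANT,
                     config.sigma_fluctuant, config.sigma_stable)
    log_baseline = rng.normal(config.baseline_log_mean,
                              config.baseline_log_sd, config.n_genes)

    ppg = np.asarray(config.probes_list())
    single_probe = bool((ppg == 1).all())
    if single_probe:
        row_ids = genes
        probe_map = pd.Series(genes, index=genes)
    else:
        row_ids = [f"{g}_p{j + 1}" for g, k in zip(genes, ppg) for j in range(k)]
        probe_map = pd.Series(np.repeat(genes, ppg), index=row_ids)
    probe_map.index.name = "probe"
    probe_map.name = "gene"

    datasets = []
    for d, n_samples in enumerate(config.samples_list()):
        rng_d = _rng(config.seed, "expression", d)
        eps = rng_d.normal(size=(config.n_genes, n_samples)) * sigma[:, None]
        gene_log = log_baseline[:, None] + eps
        if single_probe:
            log_values = gene_log
        else:
            probe_eps = rng_d.normal(size=(len(row_ids), n_samples)) * config.probe_sigma
            log_values = np.repeat(gene_log, ppg, axis=0) + probe_eps
        values = pd.DataFrame(
            np.exp(log_values),
            index=pd.Index(row_ids, name="probe"),
            columns=[f"DS{d:03d}_S{s + 1:02d}" for s in range(n_samples)])
        datasets.append(ExpressionDataset(f"DS{d:03d}", values, scale=LINEAR))

    truth = SyntheticTruth(
        gene_class=pd.Series(classes, index=genes, name="class"),
        sigma=pd.Series(sigma, index=genes, name="sigma"),
        probe_map=probe_map,
        seed=int(config.seed))
    return datasets, truth


def generate_target_map(truth: SyntheticTruth, config: SimulationConfig,
                        source: str = "synthetic"):
    """Draw a miRNA→target map with planted enrichment toward stable genes.

    For each miRNA, ``targets_per_mirna`` genes are sampled without
    replacement with weights ``target_enrichment_odds`` (stable genes) vs 1
    (fluctuant genes), using exponential-race keys (equivalent to sequential
    weighted sampling without replacement).  Odds 1 gives uniform sampling;
    odds 0 means no stable gene is ever a target.
    """
    from .propensity import TargetMap  # local import to avoid a cycle

    config.validate()
    genes = np.asarray(truth.genes)
    n = len(genes)
    k = config.targets_per_mirna
    if k > n:
        raise ConfigurationError(
            f"targets_per_mirna={k} exceeds n_genes={n}")
    odds = float(config.target_enrichment_odds)
    weights = np.where(truth.gene_class.to_numpy() == STABLE, odds, 1.0)
    if np.count_nonzero(weights) < k:
        raise ConfigurationError(
            f"targets_per_mirna={k} exceeds the {np.count_nonzero(weights)} genes "
            "with nonzero sampling weight (target_enrichment_odds=0)")

    rng = _rng(config.seed, "targets")
    mirna_to_genes: dict[str, set[str]] = {}
    for mirna in _mirna_ids(config.n_mirnas):
        keys = np.full(n, np.inf)
        nz = weights > 0
        keys[nz] = rng.exponential(size=int(nz.sum())) / weights[nz]
        chosen = np.argpartition(keys, k - 1)[:k]
        mirna_to_genes[mirna] = set(genes[chosen])

    target_map = TargetMap(source=source, mirna_to_genes=mirna_to_genes)
    status = pd.Series(False, index=truth.gene_class.index, name=source)
    status[sorted(target_map.target_genes)] = True
    truth.target_status[source] = status
    truth.planted_odds[source] = odds
    return target_map


def generate_annotations(truth: SyntheticTruth,
                         config: SimulationConfig) -> pd.DataFrame:
    """Per-gene 3'-UTR length (nt) and promoter TFBS count.

    Class-conditional two-component shift: for fluctuant genes the UTR
    log-location is shifted by ``utr_coupling`` and the TFBS mean is scaled
    by ``exp(tfbs_coupling)``.  Couplings of 0 give exact independence from
    the planted noise class.  UTR lengths are log-normal rounded to >= 1 nt;
    TFBS counts are negative-binomial (overdispersed, as motif-scan counts
    on real promoters are).
    """
    config.validate()
    rng = _rng(config.seed, "annotations")
    f = (truth.gene_class.to_numpy() == FLUCTUANT).astype(float)
    utr = rng.lognormal(mean=config.utr_log_mean + config.utr_coupling * f,
                        sigma=config.utr_log_sd)
    utr_length = np.maximum(1, np.rint(utr)).astype(int)
    mu = config.tfbs_mean * np.exp(config.tfbs_coupling * f)
    disp = config.tfbs_dispersion
    tfbs = rng.negative_binomial(disp, disp / (disp + mu))
    annot = pd.DataFrame({"utr_length": utr_length, "tfbs_count": tfbs},
                         index=truth.gene_class.index)
    annot.index.name = "gene"
    return annot


def generate_mirna_expression(config: SimulationConfig) -> pd.DataFrame:
    """Non-negative miRNA × tissue expression table (log-normal entries)."""
    config.validate()
    rng = _rng(config.seed, "mirna_expression")
    values = rng.lognormal(config.mirna_log_mean, config.mirna_log_sd,
                           size=(config.n_mirnas, config.n_tissues))
    table = pd.DataFrame(
        values,
        index=pd.Index(_mirna_ids(config.n_mirnas), name="mirna"),
        columns=[f"tissue_{t + 1:02d}" for t in range(config.n_tissues)])
    return table


@dataclass
class SimulatedCollection:
    """Everything one simulation run produces."""

    config: SimulationConfig
    datasets: list[ExpressionDataset]
    truth: SyntheticTruth
    target_map: "object"            # flmeta.propensity.TargetMap
    annotations: pd.DataFrame
    mirna_expression: pd.DataFrame


def simulate_collection(config: SimulationConfig) -> SimulatedCollection:
    """Run all generators with one config."""
    datasets, truth = generate_expression_datasets(config)
    target_map = generate_target_map(truth, config)
    annotations = generate_annotations(truth, config)
    mirna_expression = generate_mirna_expression(config)
    return SimulatedCollection(config, datasets, truth, target_map,
                               annotations, mirna_expression)


def write_collection(collection: SimulatedCollection, outdir) -> list[str]:
    """Write a simulated collection as plain TSV files; returns the manifest."""
    from .dataset import FLOAT_FORMAT

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    for ds in collection.datasets:
        path = outdir / f"expression_{ds.dataset_id}.tsv"
        write_expression_tsv(ds, path)
        manifest.append(str(path))

    path = outdir / "probe_map.tsv"
    write_probe_map(collection.truth.probe_map, path)
    manifest.append(str(path))

    truth_df = pd.DataFrame({
        "gene": collection.truth.gene_class.index,
        "class": collection.truth.gene_class.to_numpy(),
        "sigma": collection.truth.sigma.to_numpy(),
    })
    path = outdir / "truth.tsv"
    truth_df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    manifest.append(str(path))

    path = outdir / f"targets_{collection.target_map.source}.tsv"
    collection.target_map.to_tsv(path)
    manifest.append(str(path))

    path = outdir / "annotations.tsv"
    collection.annotations.to_csv(path, sep="\t")
    manifest.append(str(path))

    path = outdir / "mirna_expression.tsv"
    collection.mirna_expression.to_csv(path, sep="\t",
                                       float_format=FLOAT_FORMAT)
    manifest.append(str(path))
    logger.info("wrote %d files to %s", len(manifest), outdir)
    return manifest
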