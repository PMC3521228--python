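"""Covariates of expression fluctuation: regulator count, 3'-UTR length,
miRNA expression intensity and promoter TFBS count.

Each binned analysis groups genes by a covariate, averages the FL score per
bin and correlates (Pearson) the bin coordinate with the bin mean.  Because
correlating binned means inflates |r| relative to gene-level correlation,
every :class:`BinnedSeries` also carries a gene-level Spearman correlation as
a robustness output.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .flscore import GeneClassification
from .propensity import TargetMap
from .stats import GroupComparisonResult, compare_groups

logger = logging.getLogger(__name__)

#: bins with fewer genes are excluded from the bin-level correlation
MIN_BIN_COUNT_DEFAULT = 10


def read_annotation_tsv(path) -> pd.DataFrame:
    """Read a (gene, utr_length, tfbs_count) TSV; validates the invariants."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if (df["utr_length"] < 1).any():
        raise ValueError(f"{path}: utr_length must be >= 1 nt")
    if (df["tfbs_count"] < 0).any():
        raise ValueError(f"{path}: tfbs_count must be >= 0")
    return df


def read_mirna_expression_tsv(path) -> pd.DataFrame:
    """Read a miRNA × tissue expression TSV (non-negative intensities)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: expression intensities must be >= 0")
    return df


@dataclass
class BinnedSeries:
    """Per-bin mean FL scores plus a bin-level Pearson correlation."""

    covariate: str
    table: pd.DataFrame          # bin, x, mean_fl_score, n_genes, used
    pearson_r: float             # NaN when fewer than 2 usable bins
    pearson_p: float
    spearman_r: float            # gene-level robustness correlation
    spearman_p: float
    min_bin_count: int

    @property
    def correlation_defined(self) -> bool:
        return not np.isnan(self.pearson_r)

    @property
    def n_bins_used(self) -> int:
        return int(self.table["used"].sum())


def _fl_series(scores) -> pd.Series:
    return scores["fl_score"] if isinstance(scores, pd.DataFrame) else scores


def _binned_series(fl: pd.Series, bin_key: pd.Series, x_of_bin,
                   covariate: str, min_bin_count: int,
                   x_gene: pd.Series | None = None) -> BinnedSeries:
    """Shared binning/correlation core.

    ``bin_key`` assigns each gene to a bin, ``x_of_bin`` maps a bin key to
    the numeric x-coordinate used in the correlation, ``x_gene`` is the
    gene-level covariate for the Spearman robustness output (defaults to the
    bin key itself).
    """
    grouped = fl.groupby(bin_key)
    table = pd.DataFrame({
        "bin": grouped.mean().index,
        "mean_fl_score": grouped.mean().to_numpy(),
        "n_genes": grouped.size().to_numpy(),
    })
    table["x"] = [x_of_bin(b) for b in table["bin"]]
    table["used"] = table["n_genes"] >= min_bin_count
    table = table[["bin", "x", "mean_fl_score", "n_genes", "used"]]

    used = table[table["used"]]
    n_excluded = len(table) - len(used)
    if n_excluded:
        logger.info("%s: %d bins with < %d genes excluded from the correlation",
                    covariate, n_excluded, min_bin_count)
    if len(used) >= 2 and np.ptp(used["x"].to_numpy()) > 0 \
            and np.ptp(used["mean_fl_score"].to_numpy()) > 0:
        r, p = sps.pearsonr(used["x"], used["mean_fl_score"])
    else:
        r, p = float("nan"), float("nan")
        logger.warning("%s: bin-level correlation not computable "
                       "(fewer than 2 usable bins or constant series)",
                       covariate)
    xg = x_gene if x_gene is not None else bin_key
    if len(fl) >= 3 and np.ptp(xg.to_numpy(dtype=float)) > 0 and np.ptp(fl.to_numpy()) > 0:
        sr, sp = sps.spearmanr(xg, fl)
    else:
        sr, sp = float("nan"), float("nan")
    return BinnedSeries(covariate=covariate, table=table,
                        pearson_r=float(r), pearson_p=float(p),
                        spearman_r=float(sr), spearman_p=float(sp),
                        min_bin_count=min_bin_count)


def group_by_mirna_count(scores, targets: TargetMap,
                         min_bin_count: int = MIN_BIN_COUNT_DEFAULT) -> BinnedSeries:
    """Mean FL score of target genes binned by their number of regulators."""
    fl = _fl_series(scores)
    fl = fl[fl.index.isin(targets.target_genes)]
    if fl.empty:
        raise ValueError("no target gene carries an FL score")
    counts = pd.Series([targets.n_regulators(g) for g in fl.index],
                       index=fl.index, name="n_mirnas")
    return _binned_series(fl, counts, lambda b: float(b),
                          "mirna_count", min_bin_count)


def bin_by_utr_length(scores, annot: pd.DataFrame, targets: TargetMap,
                      bin_width: int = 300,
                      min_bin_count: int = MIN_BIN_COUNT_DEFAULT) -> BinnedSeries:
    """Mean FL score of target genes in half-open 3'-UTR-length bins.

    Bin k covers lengths [k*bin_width, (k+1)*bin_width); the correlation uses
    the bin midpoint as x-coordinate.
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    fl = _fl_series(scores)
    genes = fl.index.intersection(annot.index)
    genes = genes[genes.isin(targets.target_genes)]
    if len(genes) == 0:
        raise ValueError("no annotated target gene carries an FL score")
    fl = fl.loc[genes]
    lengths = annot.loc[genes, "utr_length"]
    bins = (lengths // bin_width).rename("utr_bin")
    return _binned_series(fl, bins,
                          lambda b: b * bin_width + bin_width / 2.0,
                          "utr_length", min_bin_count, x_gene=lengths)


def compare_utr_length(classification: GeneClassification,
                       annot: pd.DataFrame, targets: TargetMap,
                       method: str = "auto") -> GroupComparisonResult:
    """3'-UTR lengths of miRNA targets in SE genes vs in FL genes."""
    tset = targets.target_genes
    se = [g for g in classification.se_genes if g in tset and g in annot.index]
    fl = [g for g in classification.fl_genes if g in tset and g in annot.index]
    if not se or not fl:
        raise ValueError("no annotated miRNA target in the "
                         f"{'SE' if not se else 'FL'} gene set")
    return compare_groups(annot.loc[se, "utr_length"],
                          annot.loc[fl, "utr_length"],
                          "SE targets", "FL targets", method=method)


def compare_mirna_expression(classification: GeneClassification,
                             targets: TargetMap, expression: pd.DataFrame,
                             rule: str = "any",
                             method: str = "auto") -> GroupComparisonResult:
    """Average expression of miRNAs regulating SE genes vs FL genes.

    ``rule="any"`` puts a miRNA in the SE group when it targets at least one
    SE gene (and likewise for FL; a miRNA may belong to both groups).
    ``rule="majority"`` assigns each miRNA only to the class holding the
    strict majority of its SE ∪ FL targets.  A miRNA's expression is its
    average over the tissue columns.
    """
    if rule not in ("any", "majority"):
        raise ValueError(f"rule must be 'any' or 'majority', got {rule!r}")
    se = set(classification.se_genes)
    fl = set(classification.fl_genes)
    avg = expression.mean(axis=1)
    se_group, fl_group = [], []
    for mirna in targets.mirnas:
        if mirna not in avg.index:
            continue
        genes = targets.mirna_to_genes[mirna]
        n_se, n_fl = len(genes & se), len(genes & fl)
        if rule == "any":
            if n_se > 0:
                se_group.append(mirna)
            if n_fl > 0:
                fl_group.append(mirna)
        else:
            if n_se > n_fl:
                se_group.append(mirna)
            elif n_fl > n_se:
                fl_group.append(mirna)
    if not se_group or not fl_group:
        raise ValueError("one of the miRNA groups is empty")
    return compare_groups(avg.loc[se_group], avg.loc[fl_group],
                          "SE-gene miRNAs", "FL-gene miRNAs", method=method)


def tfbs_correlation(scores, annot: pd.DataFrame,
                     min_bin_count: int = MIN_BIN_COUNT_DEFAULT) -> BinnedSeries:
    """Mean FL score per distinct promoter TFBS count.

    Uses every scored, annotated gene by default (target status plays no
    role here).
    """
    fl = _fl_series(scores)
    genes = fl.index.intersection(annot.index)
    if len(genes) == 0:
        raise ValueError("no annotated gene carries an FL score")
    fl = fl.loc[genes]
    counts = annot.loc[genes, "tfbs_count"].rename("tfbs_count")
    return _binned_series(fl, counts, lambda b: float(b),
                          "tfbs_count", min_bin_count)
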