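"""FL score: rank-aggregated coefficient of variation across datasets.

For each dataset the coefficient of variation (CV = SD / mean) of every
gene's expression is computed, the CVs are rank-ordered ascending within the
dataset (average ranks for ties), and the ranks are assembled into a genes ×
datasets matrix.  A gene's FL (fluctuation) score is its average rank across
the datasets in which it was observed: small scores mark stably expressed
(SE) genes, large scores mark fluctuant (FL) genes.  Because ranks, not raw
CVs, are aggregated, heterogeneous datasets become commensurable.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dataset import ExpressionDataset

logger = logging.getLogger(__name__)

SE = "SE"
MID = "MID"
FL = "FL"


@dataclass
class CVTable:
    """Per-gene CV of one dataset (genes with zero mean omitted)."""

    dataset_id: str
    cv: pd.Series


def compute_cv(dataset: ExpressionDataset, ddof: int = 1) -> CVTable:
    """Coefficient of variation of each gene across the dataset's samples.

    CV = sample standard deviation (``ddof`` = 1 by default) divided by the
    sample mean.  Genes whose mean is exactly 0 have an undefined CV and are
    omitted (logged).  By pipeline convention the input is the gene-level
    log2 matrix, but the computation itself is scale-agnostic.
    """
    if dataset.n_samples < 2:
        raise ValueError(
            f"dataset {dataset.dataset_id!r}: CV needs at least 2 samples, "
            f"got {dataset.n_samples}")
    values = dataset.values
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=ddof)
    nonzero = mean != 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dataset %s: omitted %d genes with zero mean expression",
                    dataset.dataset_id, n_dropped)
    cv = (sd[nonzero] / mean[nonzero]).rename("cv")
    return CVTable(dataset.dataset_id, cv)


def rank_cvs(cvs: CVTable) -> pd.Series:
    """Ascending average-tie ranks of one dataset's CVs (1 = smallest CV)."""
    if len(cvs.cv) == 0:
        raise ValueError(f"dataset {cvs.dataset_id!r}: no CVs to rank")
    ranks = sps.rankdata(cvs.cv.to_numpy(), method="average")
    return pd.Series(ranks, index=cvs.cv.index, name=cvs.dataset_id)


def build_ranked_matrix(cv_tables: list[CVTable]) -> pd.DataFrame:
    """Genes × datasets matrix of CV ranks; NaN where a gene is unobserved."""
    if not cv_tables:
        raise ValueError("no CV tables supplied")
    columns = [rank_cvs(t) for t in cv_tables]
    matrix = pd.concat(columns, axis=1)
    return matrix.sort_index()


def compute_fl_scores(matrix: pd.DataFrame, min_datasets: int | None = None,
                      normalized: bool = False) -> pd.DataFrame:
    """Average each gene's CV ranks into its FL score.

    Parameters
    ----------
    matrix :
        Ranked CV matrix (genes × datasets, NaN = unobserved).
    min_datasets :
        Genes observed in fewer datasets are excluded (logged).  Default:
        half the datasets, rounded up.
    normalized :
        Divide each rank by its column's observed gene count before
        averaging, for collections with very different gene coverage.

    Returns
    -------
    DataFrame indexed by gene with columns ``fl_score`` and ``n_datasets``.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("ranked CV matrix is empty")
    if min_datasets is None:
        min_datasets = math.ceil(matrix.shape[1] / 2)
    if min_datasets < 1:
        raise ValueError(f"min_datasets must be >= 1, got {min_datasets}")
    ranks = matrix
    if normalized:
        ranks = matrix / matrix.notna().sum(axis=0)
    n_obs = matrix.notna().sum(axis=1)
    scores = pd.DataFrame({"fl_score": ranks.mean(axis=1, skipna=True),
                           "n_datasets": n_obs})
    keep = n_obs >= min_datasets
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d genes observed in fewer than %d datasets",
                    n_excluded, min_datasets)
    scores = scores.loc[keep]
    scores.index.name = "gene"
    return scores


@dataclass
class GeneClassification:
    """SE / MID / FL labels at quantile ``q`` of the FL-score ranking."""

    q: float
    labels: pd.Series      # gene -> {SE, MID, FL}, ordered ascending by score
    scores: pd.Series      # FL scores in the same order

    @property
    def se_genes(self) -> list[str]:
        return list(self.labels.index[self.labels == SE])

    @property
    def fl_genes(self) -> list[str]:
        return list(self.labels.index[self.labels == FL])

    @property
    def mid_genes(self) -> list[str]:
        return list(self.labels.index[self.labels == MID])

    @property
    def genes(self) -> list[str]:
        return list(self.labels.index)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"fl_score": self.scores, "label": self.labels})
        df.index.name = "gene"
        return df


def classify_genes(scores: pd.DataFrame | pd.Series,
                   q: float = 0.05) -> GeneClassification:
    """Label the bottom/top ``q`` quantiles of the FL-score ranking SE / FL.

    Genes are sorted ascending by FL score (ties broken by gene identifier,
    so runs are deterministic); the ``floor(q*N)`` smallest-score genes are
    labelled SE, the ``floor(q*N)`` largest FL, and the remainder MID.
    """
    if not 0.0 < q < 0.5:
        raise ValueError(f"quantile q must lie in (0, 0.5), got {q}")
    if isinstance(scores, pd.DataFrame):
        s = scores["fl_score"]
    else:
        s = scores
    n = len(s)
    if n < 2.0 / q:
        raise ValueError(
            f"degenerate classification: {n} genes < 2/q = {2.0 / q:.0f}")
    ordered = s.sort_index(kind="mergesort").sort_values(kind="mergesort")
    n_tail = int(math.floor(q * n))
    labels = np.full(n, MID, dtype=object)
    labels[:n_tail] = SE
    labels[n - n_tail:] = FL
    return GeneClassification(
        q=q,
        labels=pd.Series(labels, index=ordered.index, name="label"),
        scores=ordered.rename("fl_score"))


def score_collection(datasets: list[ExpressionDataset],
                     min_datasets: int | None = None,
                     normalized: bool = False,
                     ddof: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """CVs → ranked matrix → FL scores for a list of gene-level datasets.

    Returns ``(ranked_matrix, fl_scores)``.
    """
    tables = [compute_cv(ds, ddof=ddof) for ds in datasets]
    matrix = build_ranked_matrix(tables)
    scores = compute_fl_scores(matrix, min_datasets=min_datasets,
                               normalized=normalized)
    return matrix, scores
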