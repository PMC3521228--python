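"""Propensity of miRNA regulation among SE vs FL genes.

Three complementary analyses quantify whether miRNA targets preferentially
occupy the stable end of the FL-score ranking:

1. contingency enrichment of target status in SE vs FL genes (Fisher exact),
   with a random-sampling control of matching set sizes;
2. comparison of the FL scores of targets vs non-targets over the whole gene
   universe (Wilcoxon rank-sum);
3. a sliding window over the FL-score ranking, correlating per-window mean
   FL score with per-window target proportion (Pearson).

Also here: per-miRNA SE-/FL-miRNA classification and a generic
hypergeometric set-enrichment test with Benjamini-Hochberg correction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .flscore import GeneClassification
from .stats import (GroupComparisonResult, bh_adjust, compare_groups,
                    fisher_exact_2x2)

logger = logging.getLogger(__name__)

SE_MIRNA = "SE-miRNA"
FL_MIRNA = "FL-miRNA"
UNCLASSIFIED = "unclassified"


@dataclass
class TargetMap:
    """miRNA → target-gene map from one prediction source."""

    source: str
    mirna_to_genes: dict[str, set[str]]

    @cached_property
    def gene_to_mirnas(self) -> dict[str, set[str]]:
        inverse: dict[str, set[str]] = {}
        for mirna, genes in self.mirna_to_genes.items():
            for g in genes:
                inverse.setdefault(g, set()).add(mirna)
        return inverse

    @cached_property
    def target_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.mirna_to_genes.values():
            out |= genes
        return out

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.mirna_to_genes)

    def n_regulators(self, gene: str) -> int:
        return len(self.gene_to_mirnas.get(gene, ()))

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path, source: str | None = None) -> "TargetMap":
        """Read a two-column (miRNA, gene) TSV."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (mirna, gene)")
        mcol, gcol = df.columns[:2]
        mapping: dict[str, set[str]] = {}
        for mirna, gene in zip(df[mcol], df[gcol]):
            mapping.setdefault(mirna, set()).add(gene)
        if source is None:
            import pathlib

            stem = pathlib.Path(path).stem
            source = stem.removeprefix("targets_")
        return cls(source=source, mirna_to_genes=mapping)

    def to_tsv(self, path) -> None:
        rows = [(m, g) for m in sorted(self.mirna_to_genes)
                for g in sorted(self.mirna_to_genes[m])]
        pd.DataFrame(rows, columns=["mirna", "gene"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def union(cls, maps: Iterable["TargetMap"],
              source: str = "union") -> "TargetMap":
        """Union of several sources ("target of >= 1 miRNA in any source")."""
        merged: dict[str, set[str]] = {}
        for tm in maps:
            for mirna, genes in tm.mirna_to_genes.items():
                merged.setdefault(mirna, set()).update(genes)
        return cls(source=source, mirna_to_genes=merged)


@dataclass
class ContingencyResult:
    """2x2 enrichment of target status over SE vs FL genes."""

    source: str
    se_target: int
    se_nontarget: int
    fl_target: int
    fl_nontarget: int
    odds_ratio: float
    p_value: float

    @property
    def se_target_proportion(self) -> float:
        return self.se_target / (self.se_target + self.se_nontarget)

    @property
    def fl_target_proportion(self) -> float:
        return self.fl_target / (self.fl_target + self.fl_nontarget)

    @property
    def direction(self) -> str:
        """"SE" when targets are relatively enriched among SE genes."""
        if self.se_target_proportion > self.fl_target_proportion:
            return "SE"
        if self.se_target_proportion < self.fl_target_proportion:
            return "FL"
        return "none"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "source": self.source,
            "se_target": self.se_target,
            "se_nontarget": self.se_nontarget,
            "fl_target": self.fl_target,
            "fl_nontarget": self.fl_nontarget,
            "se_target_proportion": self.se_target_proportion,
            "fl_target_proportion": self.fl_target_proportion,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "direction": self.direction,
        }])


def _contingency(se_genes, fl_genes, target_genes: set[str],
                 source: str) -> ContingencyResult:
    a = sum(g in target_genes for g in se_genes)
    c = sum(g in target_genes for g in fl_genes)
    b = len(se_genes) - a
    d = len(fl_genes) - c
    res = fisher_exact_2x2(((a, b), (c, d)))
    return ContingencyResult(source=source, se_target=a, se_nontarget=b,
                             fl_target=c, fl_nontarget=d,
                             odds_ratio=res.odds_ratio, p_value=res.p_value)


def enrichment_test(classification: GeneClassification,
                    targets: TargetMap) -> ContingencyResult:
    """Fisher exact enrichment of miRNA targets in SE vs FL genes.

    The universe is SE ∪ FL (MID genes excluded); a gene counts as a target
    when at least one miRNA of this source regulates it.
    """
    se, fl = classification.se_genes, classification.fl_genes
    if not se or not fl:
        raise ValueError("both the SE and the FL gene set must be non-empty")
    return _contingency(se, fl, targets.target_genes, targets.source)


@dataclass
class RandomControlResult:
    """Distribution of enrichment outcomes over random gene sets."""

    source: str
    n_reps: int
    seed: int
    p_values: np.ndarray
    proportion_diffs: np.ndarray        # pseudo-SE minus pseudo-FL proportion

    def rejection_rate(self, alpha: float = 0.05) -> float:
        return float(np.mean(self.p_values < alpha))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": np.arange(1, self.n_reps + 1),
            "p_value": self.p_values,
            "proportion_diff": self.proportion_diffs,
        })


def random_control(classification: GeneClassification, targets: TargetMap,
                   n_reps: int, seed: int) -> RandomControlResult:
    """Re-run the enrichment on randomly sampled pseudo-SE/FL sets.

    Each replicate samples |SE| + |FL| genes without replacement from the
    full classified universe (SE ∪ MID ∪ FL), splits them into pseudo-SE and
    pseudo-FL sets of the original sizes and applies the Fisher test, so the
    null distribution of the enrichment statistic can be inspected.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    universe = np.asarray(classification.genes)
    n_se = len(classification.se_genes)
    n_fl = len(classification.fl_genes)
    if n_se + n_fl > len(universe):
        raise ValueError("sample size |SE|+|FL| exceeds the classified universe")
    rng = np.random.default_rng(seed)
    p_values = np.empty(n_reps)
    diffs = np.empty(n_reps)
    for i in range(n_reps):
        picked = rng.choice(universe, size=n_se + n_fl, replace=False)
        res = _contingency(picked[:n_se], picked[n_se:],
                           targets.target_genes, targets.source)
        p_values[i] = res.p_value
        diffs[i] = res.se_target_proportion - res.fl_target_proportion
    return RandomControlResult(source=targets.source, n_reps=n_reps,
                               seed=seed, p_values=p_values,
                               proportion_diffs=diffs)


def target_vs_nontarget_fl(scores: pd.DataFrame | pd.Series,
                           targets: TargetMap | Iterable[TargetMap],
                           method: str = "auto") -> GroupComparisonResult:
    """Compare FL scores of miRNA targets vs non-targets over all scored genes."""
    if isinstance(targets, TargetMap):
        target_set = targets.target_genes
    else:
        target_set = TargetMap.union(targets).target_genes
    s = scores["fl_score"] if isinstance(scores, pd.DataFrame) else scores
    is_target = s.index.isin(target_set)
    return compare_groups(s[is_target], s[~is_target],
                          "targets", "non-targets", method=method)


@dataclass
class WindowSeries:
    """Sliding-window means over the FL-score ranking."""

    window: int
    step: int
    table: pd.DataFrame      # columns: start, mean_fl_score, target_proportion
    pearson_r: float
    pearson_p: float

    @property
    def n_windows(self) -> int:
        return len(self.table)


def sliding_window(scores: pd.DataFrame | pd.Series, targets: TargetMap,
                   window: int = 2000, step: int = 50) -> WindowSeries:
    """Mean FL score vs target proportion along the sorted gene list.

    Genes are sorted ascending by FL score (ties broken by identifier); a
    window of ``window`` genes slides by ``step``, giving
    floor((N - window)/step) + 1 windows.  Pearson r (and its p-value) is
    computed across windows; note that overlapping windows are positively
    dependent, so the p-value is anti-conservative and should be read as
    descriptive.
    """
    s = scores["fl_score"] if isinstance(scores, pd.DataFrame) else scores
    n = len(s)
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    if n < window:
        raise ValueError(
            f"{n} scored genes < window size {window}; use a smaller window")
    ordered = s.sort_index(kind="mergesort").sort_values(kind="mergesort")
    values = ordered.to_numpy(dtype=float)
    is_target = ordered.index.isin(targets.target_genes).astype(float)

    cum_v = np.concatenate([[0.0], np.cumsum(values)])
    cum_t = np.concatenate([[0.0], np.cumsum(is_target)])
    starts = np.arange(0, n - window + 1, step)
    mean_fl = (cum_v[starts + window] - cum_v[starts]) / window
    prop = (cum_t[starts + window] - cum_t[starts]) / window

    if len(starts) >= 2 and np.ptp(mean_fl) > 0 and np.ptp(prop) > 0:
        r, p = sps.pearsonr(mean_fl, prop)
    else:
        r, p = float("nan"), float("nan")
        logger.warning("window correlation undefined (constant series or a "
                       "single window)")
    table = pd.DataFrame({"start": starts, "mean_fl_score": mean_fl,
                          "target_proportion": prop})
    return WindowSeries(window=window, step=step, table=table,
                        pearson_r=float(r), pearson_p=float(p))


@dataclass
class MiRNAClassification:
    """Per-miRNA SE-/FL-miRNA labels from per-miRNA Fisher tests."""

    source: str
    alpha: float
    table: pd.DataFrame      # mirna, targets_in_se, targets_in_fl, p, label

    @property
    def n_se_mirnas(self) -> int:
        return int((self.table["label"] == SE_MIRNA).sum())

    @property
    def n_fl_mirnas(self) -> int:
        return int((self.table["label"] == FL_MIRNA).sum())


def classify_mirnas(classification: GeneClassification, targets: TargetMap,
                    alpha: float = 0.05) -> MiRNAClassification:
    """Label each miRNA by where its targets concentrate (SE vs FL genes).

    For each miRNA the 2x2 table [targets in SE, targets in FL; remaining SE,
    remaining FL] is tested two-sided; a miRNA is an SE-miRNA when p < alpha
    with a higher target proportion among SE genes, an FL-miRNA in the
    opposite case, and unclassified otherwise (including miRNAs without any
    target in SE ∪ FL).
    """
    se = set(classification.se_genes)
    fl = set(classification.fl_genes)
    if not se or not fl:
        raise ValueError("both the SE and the FL gene set must be non-empty")
    rows = []
    for mirna in targets.mirnas:
        genes = targets.mirna_to_genes[mirna]
        t_se = len(se & genes)
        t_fl = len(fl & genes)
        if t_se + t_fl == 0:
            rows.append((mirna, 0, 0, float("nan"), UNCLASSIFIED))
            continue
        res = fisher_exact_2x2(((t_se, t_fl),
                                (len(se) - t_se, len(fl) - t_fl)))
        label = UNCLASSIFIED
        if res.p_value < alpha:
            if t_se / len(se) > t_fl / len(fl):
                label = SE_MIRNA
            elif t_fl / len(fl) > t_se / len(se):
                label = FL_MIRNA
        rows.append((mirna, t_se, t_fl, res.p_value, label))
    table = pd.DataFrame(rows, columns=["mirna", "targets_in_se",
                                        "targets_in_fl", "p_value", "label"])
    return MiRNAClassification(source=targets.source, alpha=alpha, table=table)


def set_enrichment(query, annotation: dict[str, set[str] | Iterable[str]],
                   universe) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query set per annotation set.

    For each annotation set A: p = P(X >= k) with k = |query ∩ A|, draws
    |query|, successes |A ∩ universe|, population |universe|; q-values are
    Benjamini-Hochberg across the annotation sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    m = len(universe)
    n_draw = len(query)
    rows = []
    for name in sorted(annotation):
        a = set(annotation[name]) & universe
        k = len(query & a)
        p = float(sps.hypergeom.sf(k - 1, m, len(a), n_draw))
        rows.append((name, len(a), k, min(1.0, p)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p_value"])
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out
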