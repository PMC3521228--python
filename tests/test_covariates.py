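"""Covariate analyses: regulator count, UTR-length bins, miRNA expression
and TFBS-count correlation."""
import numpy as np
import pandas as pd
import pytest

from flmeta.covariates import (bin_by_utr_length, compare_mirna_expression,
                               compare_utr_length, group_by_mirna_count,
                               read_annotation_tsv, tfbs_correlation)
from flmeta.flscore import GeneClassification
from flmeta.propensity import TargetMap


def _scores(values, prefix="g"):
    return pd.Series(np.asarray(values, dtype=float),
                     index=[f"{prefix}{i:03d}" for i in range(len(values))],
                     name="fl_score")


def _map(gene_sets, source="test"):
    return TargetMap(source=source,
                     mirna_to_genes={m: set(g) for m, g in gene_sets.items()})


def _classification(se, fl):
    genes = list(se) + list(fl)
    labels = ["SE"] * len(se) + ["FL"] * len(fl)
    return GeneClassification(
        q=0.5, labels=pd.Series(labels, index=genes, name="label"),
        scores=pd.Series(np.arange(len(genes), dtype=float), index=genes))


class TestGroupByMiRNACount:
    def test_single_bin_flagged_not_computable(self):
        scores = _scores(np.arange(30))
        targets = _map({"m1": list(scores.index)})
        out = group_by_mirna_count(scores, targets, min_bin_count=10)
        assert not out.correlation_defined
        assert out.n_bins_used == 1

    def test_flat_construction_gives_near_zero_r(self):
        # same mean FL score at every regulator count
        scores = _scores(np.tile([1.0, 2.0, 3.0], 40))
        idx = list(scores.index)
        targets = _map({f"m{k}": idx for k in range(3)})
        for k in range(1, 3):
            targets.mirna_to_genes[f"m{k}"] = set(idx[: 120 - 30 * k])
        out = group_by_mirna_count(scores, targets, min_bin_count=5)
        means = out.table["mean_fl_score"]
        assert means.max() - means.min() < 0.5

    def test_bin_means_match_explicit_filtering(self, scores, collection):
        targets = collection.target_map
        out = group_by_mirna_count(scores, targets, min_bin_count=1)
        for _, row in out.table.iterrows():
            members = [g for g in scores.index
                       if g in targets.target_genes
                       and targets.n_regulators(g) == row["bin"]]
            assert row["n_genes"] == len(members)
            assert row["mean_fl_score"] == pytest.approx(
                scores[members].mean())

    def test_no_scored_targets_rejected(self):
        with pytest.raises(ValueError, match="target"):
            group_by_mirna_count(_scores([1, 2]), _map({"m": ["zz"]}))


class TestBinByUTRLength:
    def _annot(self, lengths, tfbs=None, prefix="g"):
        n = len(lengths)
        return pd.DataFrame(
            {"utr_length": lengths,
             "tfbs_count": tfbs if tfbs is not None else np.zeros(n, int)},
            index=[f"{prefix}{i:03d}" for i in range(n)])

    def test_half_open_binning_convention(self):
        lengths = [1, 299, 300, 599, 600]
        scores = _scores(np.arange(5))
        annot = self._annot(lengths)
        targets = _map({"m": list(scores.index)})
        out = bin_by_utr_length(scores, annot, targets, bin_width=300,
                                min_bin_count=1)
        assert list(out.table["bin"]) == [0, 1, 2]
        assert list(out.table["n_genes"]) == [2, 2, 1]

    def test_linear_score_in_length_gives_r_one(self):
        lengths = np.arange(1, 1201, 10)
        scores = _scores(lengths.astype(float))
        annot = self._annot(lengths)
        targets = _map({"m": list(scores.index)})
        out = bin_by_utr_length(scores, annot, targets, bin_width=300,
                                min_bin_count=1)
        assert out.pearson_r == pytest.approx(1.0, abs=1e-6)

    def test_bin_means_match_explicit_filtering(self, scores, collection):
        out = bin_by_utr_length(scores, collection.annotations,
                                collection.target_map, min_bin_count=1)
        annot = collection.annotations
        tset = collection.target_map.target_genes
        for _, row in out.table.iterrows():
            members = [g for g in scores.index if g in tset
                       and annot.loc[g, "utr_length"] // 300 == row["bin"]]
            assert row["n_genes"] == len(members)
            assert row["mean_fl_score"] == pytest.approx(
                scores[members].mean())

    def test_bins_partition_the_binned_genes(self, scores, collection):
        out = bin_by_utr_length(scores, collection.annotations,
                                collection.target_map, min_bin_count=1)
        n_targets = sum(1 for g in scores.index
                        if g in collection.target_map.target_genes)
        assert out.table["n_genes"].sum() == n_targets


class TestCompareUTRLength:
    def test_identical_length_multisets_give_p_one(self):
        se = [f"s{i}" for i in range(4)]
        fl = [f"f{i}" for i in range(4)]
        annot = pd.DataFrame({"utr_length": [100, 200, 300, 400] * 2,
                              "tfbs_count": 0}, index=se + fl)
        cls = _classification(se, fl)
        res = compare_utr_length(cls, annot, _map({"m": se + fl}))
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_lengths_most_extreme(self):
        se = [f"s{i}" for i in range(20)]
        fl = [f"f{i}" for i in range(20)]
        annot = pd.DataFrame(
            {"utr_length": list(range(100, 120)) + list(range(500, 520)),
             "tfbs_count": 0}, index=se + fl)
        cls = _classification(se, fl)
        res = compare_utr_length(cls, annot, _map({"m": se + fl}))
        oracle = rank_p = 2 / __import__("math").comb(40, 20)
        assert res.p_value == pytest.approx(oracle, rel=1e-9)
        assert res.median1 < res.median2

    def test_planted_coupling_shortens_se_target_utrs(self, classification,
                                                      collection):
        res = compare_utr_length(classification, collection.annotations,
                                 collection.target_map)
        assert res.median1 < res.median2


class TestCompareMiRNAExpression:
    def _expr(self, mirnas, means):
        rows = {m: [mu, mu, mu] for m, mu in zip(mirnas, means)}
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=["t1", "t2", "t3"])

    def test_identical_expression_gives_p_one_and_equal_means(self):
        cls = _classification(["s1"], ["f1"])
        targets = _map({"mA": ["s1"], "mB": ["f1"]})
        expr = self._expr(["mA", "mB"], [5.0, 5.0])
        res = compare_mirna_expression(cls, targets, expr)
        assert res.p_value == pytest.approx(1.0)
        assert res.mean1 == res.mean2

    def test_mirna_targeting_both_classes_is_in_both_groups(self):
        cls = _classification(["s1"], ["f1"])
        targets = _map({"both": ["s1", "f1"], "seonly": ["s1"]})
        expr = self._expr(["both", "seonly"], [4.0, 8.0])
        res = compare_mirna_expression(cls, targets, expr, rule="any")
        assert (res.n1, res.n2) == (2, 1)

    def test_majority_rule_assigns_single_class(self):
        cls = _classification(["s1", "s2"], ["f1"])
        targets = _map({"m1": ["s1", "s2", "f1"], "m2": ["f1"]})
        expr = self._expr(["m1", "m2"], [4.0, 8.0])
        res = compare_mirna_expression(cls, targets, expr, rule="majority")
        assert (res.n1, res.n2) == (1, 1)

    def test_disjoint_shifted_groups_detected(self):
        rng = np.random.default_rng(2)
        se = [f"s{i}" for i in range(10)]
        fl = [f"f{i}" for i in range(10)]
        cls = _classification(se, fl)
        mapping = {f"mS{i}": [se[i]] for i in range(10)}
        mapping.update({f"mF{i}": [fl[i]] for i in range(10)})
        targets = _map(mapping)
        expr = self._expr(list(mapping),
                          list(rng.normal(10, 0.5, 10)) +
                          list(rng.normal(20, 0.5, 10)))
        res = compare_mirna_expression(cls, targets, expr)
        assert res.p_value < 1e-4


class TestTFBSCorrelation:
    def test_score_equal_to_count_gives_r_one(self):
        counts = np.repeat(np.arange(5), 12)
        scores = _scores(counts.astype(float))
        annot = pd.DataFrame({"utr_length": 100, "tfbs_count": counts},
                             index=scores.index)
        out = tfbs_correlation(scores, annot, min_bin_count=1)
        assert out.pearson_r == pytest.approx(1.0)

    def test_bin_means_match_explicit_filtering(self, scores, collection):
        out = tfbs_correlation(scores, collection.annotations, min_bin_count=1)
        annot = collection.annotations
        for _, row in out.table.iterrows():
            members = annot.index[annot["tfbs_count"] == row["bin"]]
            members = [g for g in members if g in scores.index]
            assert row["n_genes"] == len(members)
            assert row["mean_fl_score"] == pytest.approx(
                scores[members].mean())

    def test_planted_coupling_gives_positive_r(self, scores, collection):
        out = tfbs_correlation(scores, collection.annotations)
        assert out.pearson_r > 0
        assert out.spearman_r > 0


def test_annotation_reader_validates_invariants(tmp_path):
    good = tmp_path / "annot.tsv"
    good.write_text("gene\tutr_length\ttfbs_count\ng1\t100\t3\n")
    df = read_annotation_tsv(good)
    assert df.loc["g1", "utr_length"] == 100
    bad = tmp_path / "bad.tsv"
    bad.write_text("gene\tutr_length\ttfbs_count\ng1\t0\t3\n")
    with pytest.raises(ValueError, match="utr_length"):
        read_annotation_tsv(bad)
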