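"""Enrichment, random control, group comparison, sliding window and
per-miRNA classification."""
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from flmeta.flscore import GeneClassification, classify_genes
from flmeta.propensity import (SE_MIRNA, UNCLASSIFIED, TargetMap,
                               classify_mirnas, enrichment_test,
                               random_control, set_enrichment, sliding_window,
                               target_vs_nontarget_fl)
from flmeta.synthetic import STABLE


def _classification(se, fl, mid=()):
    genes = list(se) + list(mid) + list(fl)
    labels = ["SE"] * len(se) + ["MID"] * len(mid) + ["FL"] * len(fl)
    scores = pd.Series(np.arange(len(genes), dtype=float), index=genes,
                       name="fl_score")
    return GeneClassification(q=0.05,
                              labels=pd.Series(labels, index=genes,
                                               name="label"),
                              scores=scores)


def _map(gene_sets, source="test"):
    return TargetMap(source=source, mirna_to_genes={
        m: set(gs) for m, gs in gene_sets.items()})


class TestEnrichmentTest:
    def test_balanced_table(self):
        se = [f"s{i}" for i in range(10)]
        fl = [f"f{i}" for i in range(10)]
        targets = _map({"m1": se[:5] + fl[:5]})
        res = enrichment_test(_classification(se, fl), targets)
        assert (res.se_target, res.se_nontarget) == (5, 5)
        assert (res.fl_target, res.fl_nontarget) == (5, 5)
        assert res.odds_ratio == 1.0 and res.p_value == 1.0
        assert res.direction == "none"

    def test_complete_separation_is_most_extreme(self):
        se = [f"s{i}" for i in range(10)]
        fl = [f"f{i}" for i in range(10)]
        res = enrichment_test(_classification(se, fl), _map({"m1": se}))
        assert res.p_value == pytest.approx(2 / comb(20, 10), abs=1e-15)
        assert res.direction == "SE"

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            enrichment_test(_classification([], ["f1"]), _map({"m": ["f1"]}))


class TestRandomControl:
    def test_single_replicate_reproducible(self):
        se = [f"s{i}" for i in range(5)]
        fl = [f"f{i}" for i in range(5)]
        mid = [f"m{i}" for i in range(20)]
        cls = _classification(se, fl, mid)
        targets = _map({"m1": se + mid[:4]})
        a = random_control(cls, targets, n_reps=1, seed=9)
        b = random_control(cls, targets, n_reps=1, seed=9)
        assert a.p_values[0] == b.p_values[0]
        assert a.proportion_diffs[0] == b.proportion_diffs[0]

    def test_label_permutation_case_recovers_global_proportion(self):
        # |SE| + |FL| = universe: sampling degenerates to a label permutation
        se = [f"s{i}" for i in range(30)]
        fl = [f"f{i}" for i in range(30)]
        cls = _classification(se, fl)
        targets = _map({"m1": se[:10] + fl[:10]})   # global proportion 1/3
        res = random_control(cls, targets, n_reps=400, seed=1)
        assert abs(res.proportion_diffs.mean()) < 0.02

    def test_invalid_rep_count_rejected(self):
        cls = _classification(["s1"], ["f1"])
        with pytest.raises(ValueError, match="n_reps"):
            random_control(cls, _map({"m": ["s1"]}), 0, 0)


class TestTargetVsNonTarget:
    def test_identical_distributions_give_p_one(self):
        scores = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                           index=[f"g{i}" for i in range(6)], name="fl_score")
        targets = _map({"m": ["g0", "g1", "g2"]})
        res = target_vs_nontarget_fl(scores, targets)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(0)
        n = 2000
        genes = [f"g{i}" for i in range(2 * n)]
        values = np.concatenate([rng.normal(-0.5, 1, n), rng.normal(0, 1, n)])
        scores = pd.Series(values, index=genes, name="fl_score")
        res = target_vs_nontarget_fl(scores, _map({"m": genes[:n]}))
        assert res.p_value < 1e-10
        assert res.mean1 < res.mean2

    def test_union_of_sources_accepted(self, scores, collection):
        res = target_vs_nontarget_fl(scores, [collection.target_map])
        assert res.n1 + res.n2 == len(scores)


class TestSlidingWindow:
    def _scores(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.permutation(n).astype(float),
                         index=[f"g{i:04d}" for i in range(n)],
                         name="fl_score")

    def test_window_count_formula(self):
        scores = self._scores(2100)
        ws = sliding_window(scores, _map({"m": list(scores.index[:50])}),
                            window=2000, step=50)
        assert ws.n_windows == (2100 - 2000) // 50 + 1 == 3

    def test_windows_match_bruteforce_recomputation(self):
        scores = self._scores(300, seed=3)
        targets = _map({"m": list(scores.index[::3])})
        ws = sliding_window(scores, targets, window=120, step=30)
        ordered = scores.sort_index().sort_values(kind="mergesort")
        in_t = ordered.index.isin(targets.target_genes)
        for i, row in ws.table.iterrows():
            lo = int(row["start"])
            sl = slice(lo, lo + 120)
            assert row["mean_fl_score"] == pytest.approx(
                ordered.iloc[sl].mean())
            assert row["target_proportion"] == pytest.approx(
                in_t[sl].mean())

    def test_lower_half_targets_give_negative_trend(self):
        scores = self._scores(1000, seed=5)
        ordered = scores.sort_values()
        targets = _map({"m": list(ordered.index[:500])})
        ws = sliding_window(scores, targets, window=400, step=100)
        props = ws.table["target_proportion"].to_numpy()
        assert (np.diff(props) <= 1e-12).all()
        assert ws.pearson_r < 0

    def test_tiling_windows_average_to_global_proportion(self):
        scores = self._scores(900, seed=1)
        targets = _map({"m": list(scores.index[:333])})
        ws = sliding_window(scores, targets, window=300, step=300)
        assert ws.table["target_proportion"].mean() == pytest.approx(333 / 900)

    def test_too_few_genes_suggests_smaller_window(self):
        with pytest.raises(ValueError, match="smaller window"):
            sliding_window(self._scores(100), _map({"m": []}), window=200)


class TestClassifyMiRNAs:
    def test_se_concentrated_mirna_labelled(self):
        se = [f"s{i}" for i in range(500)]
        fl = [f"f{i}" for i in range(500)]
        cls = _classification(se, fl)
        res = classify_mirnas(cls, _map({"m1": se[:10]}), alpha=0.05)
        row = res.table.iloc[0]
        assert row["label"] == SE_MIRNA
        assert row["targets_in_se"] == 10 and row["targets_in_fl"] == 0
        assert row["p_value"] < 0.05

    def test_balanced_or_absent_targets_unclassified(self):
        se = [f"s{i}" for i in range(50)]
        fl = [f"f{i}" for i in range(50)]
        cls = _classification(se, fl)
        res = classify_mirnas(cls, _map({"even": se[:5] + fl[:5],
                                         "none": []}))
        assert set(res.table["label"]) == {UNCLASSIFIED}

    def test_planted_enrichment_yields_more_se_mirnas(self, classification,
                                                      collection):
        res = classify_mirnas(classification, collection.target_map)
        assert res.n_se_mirnas > res.n_fl_mirnas


class TestSetEnrichment:
    def test_query_equals_universe_is_uninformative(self):
        universe = {f"g{i}" for i in range(8)}
        out = set_enrichment(universe, {"A": universe}, universe)
        assert out["p_value"].iloc[0] == 1.0

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        out = set_enrichment({"g0", "g1"}, {"A": {"g10", "g11"}}, universe)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_hypergeometric_oracle(self):
        # |U|=20, |A|=5, |query|=5, k=4:
        # p = [C(5,4)C(15,1) + C(5,5)C(15,0)] / C(20,5) = 76/15504
        universe = {f"g{i}" for i in range(20)}
        annotation = {"A": {f"g{i}" for i in range(5)}}
        query = {"g0", "g1", "g2", "g3", "g10"}
        out = set_enrichment(query, annotation, universe)
        assert out["p_value"].iloc[0] == pytest.approx(76 / 15504, abs=1e-12)

    def test_bh_q_values_across_sets(self):
        universe = {f"g{i}" for i in range(100)}
        annotation = {"A": {f"g{i}" for i in range(10)},
                      "B": {f"g{i}" for i in range(50, 60)}}
        out = set_enrichment({f"g{i}" for i in range(10)}, annotation,
                             universe)
        assert (out["q_value"] >= out["p_value"] - 1e-15).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            set_enrichment(set(), {"A": set()}, set())
        with pytest.raises(ValueError, match="subset"):
            set_enrichment({"x"}, {"A": set()}, {"g1"})


class TestPlantedDirection:
    def test_enrichment_points_to_se_on_planted_data(self, classification,
                                                     collection):
        res = enrichment_test(classification, collection.target_map)
        assert res.direction == "SE"
        assert res.p_value < 0.01

    def test_window_correlation_negative_on_planted_data(self, scores,
                                                         collection):
        ws = sliding_window(scores, collection.target_map,
                            window=150, step=25)
        assert ws.pearson_r < 0
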