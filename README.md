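# flmeta

Meta-analysis of gene-expression **fluctuation** across heterogeneous
expression datasets, and of the propensity of miRNA regulation among stably
expressed genes.

## The problem

Genes differ widely in how sensitive their expression is to environmental
perturbation. Because raw variability measures are not comparable across
microarray studies with different designs and dynamic ranges, `flmeta`
aggregates *ranks*: for each dataset it computes every gene's coefficient of
variation across samples,

&nbsp;&nbsp;&nbsp;&nbsp;CV = s / x̄ (sample SD over mean),

rank-orders the CVs ascending within the dataset, and defines a gene's
**FL score** as its average CV rank across datasets. Genes in the bottom
quantile of the FL-score ranking (default 5%) are **SE genes** (stably
expressed); the top quantile are **FL genes** (fluctuant). The package then
asks whether miRNA targets preferentially sit at the stable end of the
ranking — the signature of post-transcriptional expression buffering — via
three analyses:

1. **Contingency enrichment** of target status in SE vs FL genes (two-sided
   Fisher exact test, computed exactly), with a random-sampling control of
   matching set sizes;
2. **Two-group comparison** of FL scores of targets vs non-targets (Wilcoxon
   rank-sum; exact permutation null for small groups);
3. **Sliding-window correlation** between mean FL score and target
   proportion along the ranking (window 2,000 genes, step 50 by default).

Covariate analyses relate fluctuation to the number of regulating miRNAs,
3'-UTR length (300-nt bins), miRNA expression intensity across tissues, and
promoter TFBS counts. A generic hypergeometric set-enrichment test with
Benjamini–Hochberg correction is included for functional annotation sets.

Because assembling a corpus of real microarray studies is a data-acquisition
exercise, the package ships a first-class synthetic-data generator that
plants known structure (stable/fluctuant noise classes, target maps with a
controllable enrichment odds ratio, annotation couplings), so every stage is
testable end to end and the statistical behaviour of the pipeline can be
calibrated under a known truth.

## Worked example

```python
from flmeta import (SimulationConfig, simulate_collection, filter_datasets,
                    classify_genes, score_collection, enrichment_test,
                    sliding_window, target_vs_nontarget_fl)
from flmeta.preprocess import preprocess_dataset

config = SimulationConfig(n_genes=2000, n_datasets=10,
                          samples_per_dataset=10,
                          n_mirnas=20, targets_per_mirna=50, seed=42)
coll = simulate_collection(config)

processed = [preprocess_dataset(ds, coll.truth.probe_map)
             for ds in filter_datasets(coll.datasets)]
matrix, scores = score_collection(processed)
cls = classify_genes(scores, q=0.05)
print(f"{len(scores)} genes scored; "
      f"{len(cls.se_genes)} SE and {len(cls.fl_genes)} FL genes")

res = enrichment_test(cls, coll.target_map)
print(f"targets: {100 * res.se_target_proportion:.1f}% of SE genes vs "
      f"{100 * res.fl_target_proportion:.1f}% of FL genes "
      f"(OR = {res.odds_ratio:.2f}, Fisher p = {res.p_value:.2e})")

cmp = target_vs_nontarget_fl(scores, coll.target_map)
print(f"mean FL score: targets {cmp.mean1:.1f} +/- {cmp.sd1:.1f}, "
      f"non-targets {cmp.mean2:.1f} +/- {cmp.sd2:.1f} "
      f"(Wilcoxon p = {cmp.p_value:.2e})")

ws = sliding_window(scores, coll.target_map, window=500, step=50)
print(f"sliding window ({ws.n_windows} windows): Pearson r = {ws.pearson_r:.2f}")
```

prints

```
2000 genes scored; 100 SE and 100 FL genes
targets: 44.0% of SE genes vs 16.0% of FL genes (OR = 4.12, Fisher p = 2.44e-05)
mean FL score: targets 950.9 +/- 364.1, non-targets 1032.3 +/- 448.4 (Wilcoxon p = 7.43e-03)
sliding window (31 windows): Pearson r = -0.24
```

The simulation planted a 3:1 enrichment of miRNA targets toward
low-noise genes; the pipeline recovers it: targets make up a much larger
share of SE genes than of FL genes, targets carry lower FL scores on
average, and the target proportion falls as the window's mean FL score
rises (negative r).

## Command line

Every stage also runs standalone on TSV files:

```sh
flmeta simulate --seed 7 --outdir sim/
flmeta preprocess --input sim/ --probe-map sim/probe_map.tsv --outdir proc/
flmeta score --input proc/ --outdir scored/
flmeta classify --scores scored/fl_scores.tsv -q 0.05 --out classification.tsv
flmeta enrich --scores scored/fl_scores.tsv --classification classification.tsv \
              --targets sim/targets_synthetic.tsv --outdir prop/
flmeta covariates --scores scored/fl_scores.tsv --classification classification.tsv \
              --targets sim/targets_synthetic.tsv --annotations sim/annotations.tsv \
              --mirna-expression sim/mirna_expression.tsv --outdir cov/
flmeta run --outdir full_run/            # the whole pipeline in one call
```

All outputs are tab-separated with a header row; missing values are written
as `NA`. Runs with the same config and seed are byte-identical.

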