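# Methods

## The FL-score procedure

For each dataset (one study's genes × samples intensity matrix) the pipeline
applies, in fixed order:

1. **Array-count filter.** Datasets with fewer than `min_arrays` samples
   (default 7, i.e. strictly more than six arrays) are dropped. The CV of a
   handful of samples is too noisy to rank meaningfully.
2. **log2 transform.** Each value v becomes log2(v) if v > 0, else 0. Values
   in (0, 1) therefore map to negative numbers and are kept as computed; the
   rule only zeroes non-positive input. A scale flag guards against double
   transformation.
3. **Probe collapse.** When several probes measure one gene, the gene's value
   in each sample is the *per-sample maximum* over its probes — not the
   single probe with the highest average. The two conventions give different
   CVs; the per-sample maximum is used deliberately and is exercised by the
   generator's probe-level noise. Probes absent from the probe→gene map are
   dropped (counted in the log); carrying them as pseudo-genes would dilute
   the gene-level score.

Because log2 is monotone on positives, steps 2 and 3 commute for positive
data; the fixed order pins down the v ≤ 0 edge case.

For each retained dataset the per-gene **CV** is the sample standard
deviation (n−1 denominator; the divisor is configurable via `ddof`) divided
by the sample mean of the (log2) values. Genes with mean exactly 0 have an
undefined CV and are omitted from that dataset's column. CVs are rank-ordered
ascending within the dataset with average ranks for ties (the standard
convention for rank statistics; any valid column then satisfies
Σranks = n(n+1)/2, which the tests assert). The **FL score** of a gene is the
mean of its ranks over the datasets where it was observed; genes observed in
fewer than `min_datasets` datasets (default: half, rounded up) are excluded,
since a one-dataset "average" rank is not a meta-analytic quantity. An
optional normalized mode divides each rank by its column's observed size
before averaging, for collections whose datasets cover very different gene
sets; raw ranks are the default.

**Classification.** Genes are sorted ascending by FL score, ties broken by
gene identifier so runs are deterministic. The floor(qN) smallest-score genes
are SE, the floor(qN) largest are FL (default q = 0.05; 0.10 is a common
robustness setting), the rest MID. Fewer than 2/q genes is rejected as
degenerate. Low FL score = stable: the SE label sits at the *bottom* of the
ranking.

CV is computed on the log2 scale because the transform precedes scoring in
the pipeline; on the linear scale the CV is scale-invariant
(CV(c·x) = CV(x)), which the tests assert as the pre-log invariance.

## Propensity analyses

* **Contingency enrichment** builds the 2×2 table of target status over
  SE ∪ FL (MID excluded — the analysis contrasts the two tails). "Target"
  means regulated by ≥ 1 miRNA of the given source; the union across sources
  is available as its own source. The two-sided Fisher p sums the
  probabilities of all tables (given the margins) that are at most as
  probable as the observed one. This is computed with exact integer
  arithmetic, so probability ties are resolved exactly rather than through a
  floating-point inclusion threshold; scipy's implementation serves as an
  independent cross-check in the tests. The odds ratio is the raw
  cross-product a·d/(b·c), reported as `inf`/`nan` when a zero cell makes it
  undefined (no continuity correction is applied silently).
* **Random control** draws |SE| + |FL| genes without replacement from the
  whole classified universe, splits them into pseudo-tails of the original
  sizes and repeats the Fisher test, giving the null distribution of the
  enrichment under "no association between tail membership and targeting".
* **Two-group comparison** contrasts FL scores of targets vs non-targets
  over all scored genes (no sampling involved). The Wilcoxon rank-sum test
  uses an exact branch when both groups have ≤ 25 observations: the full
  permutation null of the rank sum is computed by dynamic programming over
  the tie-averaged pooled ranks, which is identical to enumerating all
  C(n+m, n) assignments (enumerating them literally is infeasible at 25+25)
  and remains exact under ties. The permutation distribution is symmetric
  about n₁(N+1)/2 — reversing the rank order maps the rank multiset onto
  itself — so the two-sided p is the probability of an absolute deviation at
  least as large as observed. Larger groups use the normal approximation
  with tie and continuity correction.
* **Sliding window** sorts genes ascending by FL score (window 1 = most
  stable; the direction only flips the series, not the correlation) and
  reports mean FL score and target proportion per window of W genes stepped
  by S (defaults 2,000/50), plus Pearson r and p across windows. Overlapping
  windows are positively dependent, so that p-value is anti-conservative and
  is reported as descriptive only. When S = W the windows tile the list and
  the window proportions average back to the global target proportion (a
  test invariant).
* **SE-/FL-miRNA classification** tests, per miRNA, the table
  [targets in SE, targets in FL; remaining SE, remaining FL]. A miRNA with
  p < α and the higher target proportion among SE genes is an SE-miRNA,
  the mirror case an FL-miRNA, anything else (including miRNAs with no
  target in either tail) unclassified. The exact 2×2 construction for this
  per-miRNA test is a design choice; counting target *sites* instead of
  target genes would be an alternative reading.
* **Set enrichment** is a generic upper-tail hypergeometric test
  (P(X ≥ k) with k = |query ∩ A|, population = explicit universe) with
  Benjamini–Hochberg q-values across the annotation sets. It takes an
  explicit universe because, unlike the tail-contrast above, annotation
  enrichment is relative to all scored genes.

## Covariate analyses

Binned analyses group genes by a covariate, average the FL score per bin and
correlate the bin coordinate with the bin mean (Pearson). Bins with fewer
than `min_bin_count` genes (default 10) are excluded from the correlation —
singleton bins would otherwise dominate r. Correlating binned means inflates
|r| relative to a gene-level correlation; since the binned-mean procedure is
the analysis of record here, it is reported as such, and each result also
carries a gene-level Spearman correlation as a robustness output.

* **Regulator count:** bin key = number of distinct regulating miRNAs of
  each target gene; x = the count.
* **3'-UTR length:** only predicted targets are binned, in half-open
  intervals [k·w, (k+1)·w) with w = 300 nt; x = the bin midpoint. A direct
  SE-target vs FL-target comparison of UTR lengths (medians/means + Wilcoxon)
  complements the binned series.
* **miRNA expression:** a miRNA joins the SE group if it targets ≥ 1 SE gene
  and the FL group if it targets ≥ 1 FL gene (it may be in both); a
  majority-of-targets rule is available by flag. Each miRNA's expression is
  its mean over the tissue columns.
* **TFBS count:** every scored, annotated gene (target status plays no
  role); each distinct count is a bin. Restricting to targets is a
  configuration away, since which gene set this analysis should use is
  genuinely open.

## The synthetic-data generator

The generator emulates the statistical structure of a meta-analysis corpus —
not any particular platform or study. Intensities are multiplicative
log-normal: gene g has one baseline B_g = exp(N(μ₀, s₀)) (defaults μ₀ = 6.5,
s₀ = 1.0 on the natural-log scale, i.e. linear intensities of a few hundred),
and sample values B_g·exp(N(0, σ_g)) with σ_g = `sigma_stable` (0.1) or
`sigma_fluctuant` (0.6) by planted class (`fluctuant_fraction` = 0.10). Under
this model the linear-scale CV is √(exp(σ²) − 1), monotone in σ, so the
planted classes are exactly what the CV-rank statistic estimates. Probe
values multiply the gene signal by exp(N(0, `probe_sigma`)) (default 0.1,
2 probes/gene), so probe collapsing operates on correlated rows as it would
on a real array.

Target maps sample `targets_per_mirna` genes per miRNA without replacement
with weights odds:1 (stable:fluctuant), implemented by exponential-race keys
(equivalent to sequential weighted sampling). The planted
`target_enrichment_odds` (default 3) is the per-draw odds; the pooled
per-miRNA target indicator recovers it (a test checks within 20%), while the
*gene-level* "targeted by ≥ 1 miRNA" status compounds across miRNAs and
shows a larger odds ratio — as the acceptance script's output illustrates.

Annotations use a class-conditional two-component shift: UTR length is
log-normal (median 750 nt, log-SD 1.0 — a heavy-tailed spread comparable to
human 3'-UTRs) with the log-location shifted by `utr_coupling` for fluctuant
genes; TFBS counts are negative-binomial (mean 8, dispersion 3 —
overdispersed, as motif-scan counts are) with the mean scaled by
exp(`tfbs_coupling`). Coupling 0 gives exact independence; the default 1.0
produces the positive fluctuation–covariate trends the covariate analyses
are designed to detect. A copula would allow richer dependence but is
unnecessary for monotone-trend recovery. The miRNA × tissue table is
log-normal with 31 tissue columns by default.

All randomness derives from one seed: each generator draws from a stream
keyed by (seed, purpose code, dataset index), so outputs are bit-identical
across runs and independent across generators.

### What the generator does not emulate

Array-specific artifacts (background, saturation, batch effects, normalization
differences), correlated genes (co-expression modules), varying gene coverage
between datasets (all synthetic datasets share the full gene universe, so the
missing-gene policy is exercised only by constructed test fixtures), and any
relationship between miRNA expression level and targeting. Passing tests
demonstrate that the pipeline recovers planted structure under this idealized
model — not that any particular biological dataset will show these effects.
One structural consequence of the planting: because stable genes are favored
as targets of *every* miRNA, a gene's regulator count is itself negatively
associated with its noise class in synthetic data, so the regulator-count
analysis shows a negative trend there rather than the flat profile real data
may show.

## Numerical and interface choices

* Fisher p-values are exact rationals evaluated once in floating point; no
  tolerance enters the test decision itself.
* Wilcoxon exact branch: DP table of C(50,25) ≈ 1.3·10¹⁴ < 2⁵³ counts, so
  float64 arithmetic is still integer-exact at the 25 + 25 limit.
* Degenerate inputs are reported, not raised, where the quantity is simply
  undefined: a single usable bin yields `r = NaN` with a flag; a miRNA with
  no tail targets is "unclassified"; Fisher tables with an empty margin give
  p = 1.
* All writers emit tab-separated text with a fixed float format (`%.10g`)
  and `NA` for missing values, making seeded runs byte-identical.
* The pipeline report (`report.json`) lists per-stage parameters, exclusion
  counts and the output-file manifest, and records the failing stage if a
  run aborts.

## Problem sizes

The reference simulation used by `scripts/acceptance.py` and the heavier
tests is 20 datasets × 5,000 genes × 10 samples (with 50 miRNAs × 200
targets); replicate-based calibrations use 100–500 seeded replicates of the
target-map or annotation generators against one fixed expression collection.
These sizes give stable rates (binomial SE of a few percent on the
calibration fractions) while keeping a full run in the seconds-to-minutes
range.

## Limitations

* The FL score inherits the CV's sensitivity to the log transform: genes
  with log2 means near 0 can produce extreme CVs. Real pipelines might floor
  intensities; this package follows the stated transform rule exactly.
* Raw-rank averaging assumes datasets have comparable gene coverage; with
  very uneven coverage, use `normalized=True`.
* The sliding-window and binned-mean Pearson p-values ignore the dependence
  between overlapping windows / the reduction from gene-level to bin-level
  data, and are descriptive only.
* The random control resamples gene sets against a fixed target map; it does
  not model uncertainty in the target predictions themselves.
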