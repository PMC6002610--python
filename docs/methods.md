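# Methods

`eeseq` reimplements, as a tested library, the transcriptomic arm of a
paired environmental-enrichment (EE) versus barren-housing (B) study design:
gene-level expression matrices from a 6-litter × {EE, B} × {1 h, 4 h} brain
RNA-seq experiment are filtered, TMM-normalised, tested for differential
expression with a double-threshold rule, scored against directed gene
signatures with a randomisation test on median fold changes, and summarised
as thresholded Pearson correlation networks clustered with the Markov
Cluster algorithm. A synthetic-data generator with the same design provides
ground truth for every stage.

## Expression filtering

Genes whose expression is below 2 TPM in one or both treatment groups are
removed as noise before any testing. The group summary is the **median**
TPM across a treatment group's samples (configurable to the mean): the rule
as usually stated does not fix the summary, and the median is robust to a
single high library. The comparison is inclusive (`>= 2` is kept), and the
filter pools both timepoints so that one gene universe serves all three
comparisons (1 h, 4 h, and pooled). The filter is idempotent.

## TMM normalisation

Scaling factors follow the published trimmed-mean-of-M-values definition:
the reference sample is the one whose 75th percentile of library-scaled
counts is closest to the mean of those percentiles; for each other sample,
gene-wise M (log2 ratio of relative expression) and A (average log2
abundance) values are computed over doubly-positive genes, the extreme 30%
of M and 5% of A are discarded by rank, and the surviving M-values are
averaged with inverse asymptotic binomial-variance weights. Factors are
centred to log-mean zero (their product is 1). The implementation agrees
with Bioconductor edgeR's `calcNormFactors(method="TMM")` to printed
precision on random matrices, and with an independent loop-based oracle to
1e-10 in the test suite. CPM uses the TMM-effective library size:
`count / (libsize * factor) * 1e6`.

## Differential expression calling

A gene is called differentially expressed when both of

* |log2 fold change| >= log2(1.2), computed as
  `log2((mean_A + c) / (mean_B + c))` on TMM-CPM with prior count c = 0.5
  (damps fold changes of near-zero genes), and
* p < 0.02 from a two-sided gene-wise test,

hold; the fold-change bound is inclusive, the p bound strict. No
multiple-testing correction is applied — the unusually strict double
threshold *is* the conservatism of this calling scheme, and the calls feed
set-level statistics rather than per-gene claims. The default test is
Welch's t on log2(CPM + 0.5); genes with zero variance in both groups get
p = 1 when the group means agree and p = 0 when they differ (perfect
separation). An alternative `nb_exact_mom` test is provided for very small
groups: counts are scaled to a common effective library size, a common
negative-binomial dispersion is estimated by the median method-of-moments
across genes (floored at 1e-4), and the split of each gene's total between
the groups is compared against its conditional null distribution (totals
above 200,000 fall back to a normal approximation). Neither test attempts
bit-compatibility with any empirical-Bayes dispersion machinery; both are
calibrated by simulation in the test suite (null rejection at 0.05 within
[0.03, 0.07] on 8+/10 seeds).

## Signature randomisation test

For a directed signature with x genes present in the analysed universe,
s = 10,000 subsets of x genes are drawn uniformly without replacement from
the **full** universe (signature genes included) and the signature's median
log2 fold change is compared to each subset's. q counts subsets the
signature beats — strictly higher median for an "up" signature, strictly
lower for "down"; ties never count, keeping the p-value valid (slightly
conservative). With r = s − q,

    p = (r + 1) / (s + 1),

with attainable floor 1/(s+1) = 9.99e-05 at s = 10,000, reached exactly
when the signature beats every subset. Medians are compared on the log2
scale; log2 being strictly monotone, this is equivalent to comparing raw
fold-change medians. Subsets are materialised by taking the x smallest of n
iid uniform keys per draw (a uniform x-subset), chunked to bound memory;
the seed is stored in the result for exact replay. Properties verified by
test: exact agreement with exhaustive enumeration on a 6-gene universe,
super-uniformity under a random-signature null, antisymmetry under
negation + direction flip at a fixed seed, and monotonicity in the
signature effect.

## Correlation networks and Markov clustering

Pearson correlations are computed on log2(value + 1) by default (raw scale
configurable). Edges require **signed** r >= threshold — anti-correlated
pairs are never connected. Conventional thresholds: 0.99 for sample-sample
graphs over all genes, 0.93 over differentially expressed genes only, and
0.90 for gene-gene graphs. Zero-variance profiles keep their node but get
no edges (logged).

MCL: self-loops are set to each node's maximum incident weight (1 for
isolated nodes), columns normalised to a stochastic matrix, then expansion
(matrix squaring) alternates with inflation (elementwise power 2.2 and
renormalisation), pruning entries below 1e-8, until the largest entry
change is below 1e-6 or 100 iterations (non-convergence returns the current
state with a warning). Clusters are the connected components of the limit
matrix's symmetrised nonzero pattern, numbered 1..k by decreasing size with
ties broken by the smallest member label, which makes the numbering
invariant to node input order. Clusters smaller than `min_size` (default 3)
remain assigned but are flagged. Inflation 2.2 is the granularity used for
the gene-to-gene analysis this package mirrors; the remaining numerical
constants are conventional MCL practice.

## Synthetic-data generator

The generator emulates the paired study design, not any particular dataset.
For gene g in sample j (litter l), counts are negative binomial with mean

    mu_gj = L_j * w_g * exp(u_lg) * 2^{delta_g(treatment_j, time_j)} / sum(w)

and variance mu + phi*mu², where `w_g = exp(ln-mean)` with ln-mean uniform
on (1.0, 7.0) — a ~400-fold abundance range; `u_lg ~ N(0, litter_sd²)` is a
per-(litter, gene) effect shared by all four samples of a litter, which is
what makes whole-transcriptome sample networks cluster by litter; and delta
injects +1 log2 on the IEG signature in EE samples at 1 h only (transient
induction) and −1 log2 on the microglial signature in EE samples at both
timepoints (persistent depression). Because litter effects and library
depths are shared or identically distributed across treatments, the
expected EE/B mean ratio of an affected gene is exactly 2^delta.

Defaults, chosen once from the design being emulated and an a priori
power/correlation analysis: 2,000 genes (a desk-scale stand-in for ~22,000;
the full size is supported), 6 litters (24 samples), dispersion phi = 0.05,
litter_sd = 0.15 (ln scale), library sizes uniform on 4–8 million so that
per-gene depth matches a >30 M-read experiment at 22k genes, gene lengths
log-uniform on 500–10,000 nt (used only so TPM ≠ CPM), and signature sizes
11 (IEG) and 52 (microglial) — the study-scale 123/569 scaled by the
2,000/21,971 gene ratio, keeping the *prevalence* of perturbed genes
realistic. Keeping the absolute sizes at n = 2,000 would make ~35% of the
universe differentially expressed, contaminating the randomisation
background in a way a 22k-gene dataset does not.

What the generator does **not** emulate: read-level noise and mapping
ambiguity (no FASTQ), isoform-level effects and length-offset corrections
(gene counts are plain transcript sums), sex differences (all samples male,
as in the sampled design), gene-gene co-expression beyond what litter and
treatment effects induce, and heterogeneous per-gene effect sizes within a
signature. Passing recovery tests therefore demonstrates the pipeline's
correctness under its own model assumptions, not performance on real data.

## Reproducibility

Every stochastic component takes an explicit seed (numpy `default_rng`).
The pipeline derives per-stage seeds from one master seed by hashing the
stage name (blake2b, reduced below 2³¹), so stages can be rerun in
isolation; the manifest records the config, its hash, the package version
and all stage seeds, and two runs with the same config are byte-identical
in every TSV output.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the randomisation floor at the
full s = 10,000 with a 2,000-gene universe and x = 123; null calibration
uses 1,000 replicates at s = 999 on a 500-gene universe (x = 15); the
end-to-end recovery runs the complete pipeline on the default 2,000-gene,
24-sample configuration; network-recovery suites use 10 seeds each. These
sizes were picked so the whole suite exercises every stage at full
statistical fidelity while remaining quick to run.

## Known limitations

* The Welch test on log-CPM is slightly conservative for very low counts;
  the 2-TPM filter removes most such genes before testing.
* The `nb_exact_mom` test uses a single common dispersion; with strong
  gene-wise dispersion heterogeneity its calibration degrades.
* MCL post-processing choices (self-loop weight, pruning) follow common
  practice but are not canonical; only structural properties (component
  preservation, planted-partition recovery) are guaranteed by tests.
* GraphML export stringifies numeric node attributes per the format's type
  mapping; cluster ids and edge weights round-trip losslessly.
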