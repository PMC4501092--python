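# Methods

## Overview

`epinstab` asks which epigenetic-enzyme (EE) genes — chromatin and DNA
methylation writers, readers, erasers and editors — control the genome-wide
DNA-methylation changes of tumors, consistently across cancer types.  The
analysis integrates, per cohort, a gene-expression matrix (RSEM-like
counts) and an Illumina-450k-style beta-value matrix with normal/cancer
labels, and combines cohorts in a meta-analysis.  All stages run on
synthetic matched cohorts with planted ground truth; the real-data path
differs only in data loading.

## Instability indices

Probes of one region class on one chromosome are grouped greedily
left-to-right into regional clusters: a probe joins the open cluster iff
its gap to the previous probe is ≤ 500 bp *and* the resulting span
(max − min position) stays ≤ 1500 bp.  This is the bounded-cluster
construction familiar from bump-hunting tools; an independent brute-force
re-implementation serves as an oracle in the tests.

Cluster-level methylation is the mean beta of member probes.  With
μ_r, σ_r the mean and **sample** standard deviation (n−1 denominator;
the convention of the surrounding R ecosystem) of cluster r over normal
samples, each cancer sample s gets Z_rs = (β_rs − μ_r)/σ_r.  Clusters
with σ_r = 0 are excluded from numerator and denominator alike and
counted in the logs.  Indices:

* HyperZ_s: mean of Z_rs·H(Z_rs) over promoter-CGI clusters (promoter
  CGIs are near-unmethylated in normal tissue, so only positive
  deviations are biologically "hyper");
* HypoZ_s: mean of |Z_rs|·H(−Z_rs) over open-sea clusters (near-fully
  methylated in normals);
* H(0) = 0 exactly, so a cancer sample sitting at the normal means scores
  zero and both indices are non-negative by construction.

The *significant* variant restricts both the summation and n_r, per
sample, to clusters with a one-sided normal tail P < 0.05 in the
direction of interest (|Z| > 1.6449; one-sided because the direction is
prespecified per region class).  Samples with no significant cluster
score zero.  Both variants are always computed; correlation analyses use
the significant variant by default because it decouples the two indices
most strongly, while index-vs-index association plots use the all-regions
variant.  Shore/shelf probes are annotated but feed no index.

## Preprocessing and QC

* Betas from intensities: Max(M,0)/(Max(M,0)+Max(U,0)+100), the standard
  regularised ratio, giving values in [0,1).
* Expression: zeros replaced by the dataset-wide (not per-gene) minimal
  positive value, then log2.
* Methylation missingness: probes missing in > 70% of samples are
  dropped; remaining gaps are imputed probe-wise as the average of the
  k = 10 nearest probes (plain Euclidean distance over the samples both
  probes observe) that observe the missing sample, clipped to [0,1].
  When no neighbour observes the sample, the probe's own mean is used
  and a warning raised.  Observed values are never altered.  This is a
  deliberate re-implementation rather than a library call: off-the-shelf
  KNN imputers rescale distances by missingness and fall back to the
  sample mean, both of which differ from the behaviour specified here.
* SVD QC: rows are centred (and standardised), and the number of
  significant components of variation is the count of eigenvalues of the
  sample correlation structure above the Marchenko–Pastur upper edge
  (1+√(n/p))².  Because the top eigenvalue of a finite pure-noise matrix
  fluctuates around that edge (Tracy–Widom), the threshold includes the
  standard finite-sample allowance at the 5% level (Johnstone's
  largest-eigenvalue calibration, TW1 95th percentile 0.9793); on i.i.d.
  200×100 Gaussian matrices this yields zero significant components in
  ≈96% of draws.  Retained components are associated with sample factors
  by rank-sum (2-level), Kruskal–Wallis (>2 levels) or Spearman
  (numeric) tests.  A no-op hook marks where Infinium type-II probe
  normalisation would slot into a real-data adapter; synthetic data has
  no probe-type bias.

## Differential-expression and correlation meta-analysis

Per cohort, genes are tested normal-vs-cancer with a moderated t-test:
pooled gene variances s_g² (df d_g) are shrunk toward a prior,
s̃² = (d₀s₀² + d_g s_g²)/(d₀+d_g), t = Δmean/(s̃·√(1/n₁+1/n₂)) on
d_g + d₀ df.  The hyperparameters (d₀, s₀²) are estimated by closed-form
moment matching of a scaled inverse-chi-square to the observed variance
distribution on the log scale (digamma/trigamma moments); one test checks
the result against the reference R implementation to 1e-8.  All cancer
samples are used, not only those with matched methylation.

Gene–index association uses Pearson correlation over matched cancer
samples only, transformed to Fisher Z = 0.5·log((1+r)/(1−r)) with
two-sided normal P values at variance 1/(n−3).  Per-cohort significance
is deliberately relaxed (unadjusted P < 0.05) because the meta-analysis
re-assesses significance across cohorts: a gene is *consistent* when
significant in the same direction in ≥ m of T cohorts (m = 8 for
differential expression, m = 6 for correlations; clamped with a warning
when T < m).

The analytic null: per cohort, the fraction of **all** genes significant
in each direction is recorded; averaging across cohorts gives p̄, and the
probability that a random gene is consistent is the exact binomial tail
Σ_{k=m}^{T} C(T,k) p̄^k (1−p̄)^{T−k}.  The count of consistent genes in a
pool of n (212 for the curated EE list) is then Binomial(n, tail), giving
the expected random count n·tail ± √(n·tail(1−tail)) and an exact
upper-tail meta P value (computed in log space, so tails far below
double-precision granularity of 1 remain accurate).  The tail itself is
an exact finite sum, oracle-checked against an independent CDF to 1e-12.

The expression–expression meta network combines per-cohort Fisher Z
values by a √(n−3)-weighted Stouffer statistic, keeps edges passing a
Bonferroni threshold over pairs with sign agreement in more than half the
cohorts — Stouffer/Bonferroni chosen because the pair universe is small
(the candidate set) and no combination rule is canonical here.

## Causal filtering

Partial correlation of y and x given covariates Z: both variables are
residualised by least squares on [1, Z] (covariates standardised for
conditioning-number hygiene; the result is identical in exact
arithmetic), then the Pearson correlation of the residuals is taken,
with P from Fisher Z at variance 1/(n−k−3).  Collinear covariate sets
are reduced to an independent subset by rank-revealing pivoted QR and the
reduction is logged — with 2K covariates in the full model a silent
degenerate fit would be worse than a loud one.  Two tests:

* **single-gene**: covariate = the gene's own promoter DNAm (mean beta
  of the promoter-CGI cluster(s) assigned to the gene by the annotation;
  the annotation carries the promoter→gene map, the pipeline never
  computes TSS windows).  Distinguishes "expression reads out promoter
  methylation" (confounding) from direct influence.
* **full model**: for each of the K candidate genes, covariates are the
  other K−1 genes' expression plus all K promoter DNAm levels
  (requires n > 2K+3).  Also removes edges mediated by another gene's
  expression.

A gene *survives* when the partial P < 0.05 with the marginal sign.  The
consensus network keeps (gene, index, sign) edges supported by ≥ 6 of 10
cohorts of the full model; the single-gene results are reported
alongside.  The 0.05 threshold for partial correlations mirrors the
marginal convention (no separate adjustment is prescribed anywhere).

Candidate regulators — the input to the causal stage — are EE genes
passing *both* marginal screens with matching directionality
(overexpressed genes must correlate positively, underexpressed
negatively), the pattern the marginal analysis itself exhibits.

## Locus-level consistency

For a regulator associated with HyperZ, only CGI clusters are eligible
(open-sea clusters for HypoZ-associated genes).  Per cluster, the Fisher
Z of the correlation with the regulator's expression over cancer samples
is computed; clusters are ranked by the reference cohort's statistics
(descending for positively associated regulators, ascending for
negative) and each other cohort's statistics are compared with the
reference by Spearman rho (average ranks on ties).  Cross-cohort cluster
identity is by probe membership, guaranteed by the shared probe manifest.

## Synthetic data: what it emulates, and what it does not

Defaults (the study conditions): 10 cohorts × (20 normals + 80 cancers),
300 genes of which 40 EE, 200 promoter-CGI + 200 open-sea regions × 3
probes (regions 10 kb apart, probes 100 bp apart, one pseudo-chromosome
per class — clustering is exercised but unambiguous).  Normal betas sit
at 0.10 (CGI) and 0.80 (open sea) with probe-level noise sd 0.03.  Each
cancer sample draws independent half-normal latents h_s, l_s
(scale σ = 0.25, so the mean affected-region shift ≈ σ√(2/π)·E[w] ≈ 0.15
with region weights w ~ U(0.5, 1)); h_s shifts a fixed half of the CGI
regions upward, l_s a fixed half of the open-sea regions downward, and
affected sets, weights and gene baselines are shared across cohorts
(fixed-platform behaviour).  Expression is simulated on the log2 scale
(baselines U(4,10), noise sd 0.5) and exponentiated to an RSEM-like raw
matrix so the preprocessing path is exercised; 1% of beta entries are
masked as missing.

Each affected region responds to the sample's latent magnitude with a
region-by-sample multiplicative factor max(N(1,1), 0).  This tumor
heterogeneity term is essential, not cosmetic: without it a single
region's methylation is an almost noiseless readout of the genome-wide
latent, so conditioning on *any* affected promoter (e.g. the confounded
gene's) silences the true drivers and the causal stage loses
identifiability — a regime real arrays are never in, since genome-wide
indices average thousands of imperfectly responding loci.

The planted panel realises the three causal archetypes: UHRF1-like and
WHSC1-like direct hyper drivers and a CBX7-like direct hypo
tumor-suppressor (expression = baseline ± slope·latent + noise,
slope 5 — about a 2-fold median expression shift in cancer); an
EYA4-like confounded gene whose expression is −6× its own (affected)
promoter beta; and a PCNA-like mediated gene riding on UHRF1-like
expression with coupling 0.5.  Direct drivers' and the mediated gene's
promoter regions are kept unaffected so their promoter methylation
carries no signal; the confounded gene's promoter is forced into the
affected set.  The slopes/couplings were fixed once so that each planted
effect is strongly powered per cohort (per-cohort correlation and
differential-expression power near 1 for drivers) while the decoys still
pass the marginal screens — the regime the method is designed for.

Not emulated: probe-type chemistry and normalisation bias, batch
effects, copy-number or mutational influence on expression, cell-type
composition, and correlated hyper/hypo processes.  Passing tests
therefore demonstrate correctness of the statistical machinery and
recoverability of planted structure under the stated model — not
robustness to those real-data complications.

## Numerical and degenerate-input choices

* Binomial tails: exact `math.comb` sums (floats), clipped to [0,1];
  meta P values via log-sum-exp.
* Correlations with |r| ≥ 1 − 1e-12 or zero variance are flagged
  `undefined` and excluded from consistency counts; constant indices
  yield NaN association statistics, reported as such.
* The significant-index variant defines 0/0 (no significant cluster) as
  index 0.
* Moderated-t prior df is capped at 1e6 and treated as "effectively
  infinite" (full shrinkage) beyond; d₀ = 0 reduces exactly to the
  ordinary pooled t.
* Everything is seeded through a single `numpy` Generator per
  simulation; reruns with the same config are bit-identical.

## Problem sizes

Tests and the acceptance script run the full 10-cohort default study
(≈3 s per seed): 20 seeds in the recovery test, 10 in the acceptance
script, 100-seed Monte-Carlo for the random-matrix null, and a
600-gene × 2-cohort null study for false-positive-rate calibration.
These sizes give comfortable Monte-Carlo margins for every asserted
property while keeping the whole suite fast.

## Known limitations

* The per-cohort null probabilities p̄ are estimated from the same data
  the consistency counts come from (as in the original design); with few
  genes this couples the null mildly to the signal genes.
* The binomial null treats cohorts as independent and exchangeable;
  shared normals or overlapping platforms would violate this.
* Partial correlation only removes *linear* indirect effects, and the
  consensus network makes no directionality claim beyond the
  covariate-adjustment logic.
* With strongly collinear candidate genes (e.g. two drivers coupled to
  the same latent process), full-model partial correlations shrink; the
  method needs per-gene residual signal to keep an edge.
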