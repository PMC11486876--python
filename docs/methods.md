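# Methods

## Scope and data model

`lsmsurv` analyzes an already-normalized log2 expression matrix (genes ×
samples) against right-censored overall survival. Upstream array processing
(CEL files, RMA, quantile normalization, batch correction) is out of scope:
the package consumes RMA-style log2 values and warns when the value range
(max > 25) suggests linear-scale data. Missing values are rejected rather
than imputed. Probe-level matrices are collapsed to gene symbols either by
keeping the probe with the highest mean expression (`max_mean`, the default
and the common Affymetrix convention) or by the per-cell median across a
gene's probes; collapse is idempotent on gene-level input.

## Per-gene survival screen

Each panel gene is dichotomized at a data-driven cutoff, the median by
default, with values equal to the cutoff assigned to the *low* group — the
least informative split, chosen because published analyses of this kind
rarely state their cutpoint. The high and low groups are compared by the
two-group log-rank test (1 df) and the Kaplan–Meier product-limit estimator;
the hazard ratio comes from a univariate Cox fit on the same dichotomized
groups (a switch allows the continuous log2 covariate instead), with Efron
tie handling and Wald 95% confidence intervals on the log-hazard scale —
symmetric in log HR, matching forest-plot conventions. Estimation is
delegated to lifelines; the screening conventions are owned here.

Labels follow the sign of the hazard ratio (favorable iff HR < 1). Index
inclusion defaults to log-rank p < α (α = 0.05) with no multiple-testing
correction across the small panel — deliberately mirroring the single-panel
screening practice of the array literature — and can be overridden by
explicit harmful/favorable lists to pin a published signature
(`lsmsurv.pipeline.PAPER_GENE_SETS` ships the 3-harmful/1-favorable LSM
configuration). Degenerate Cox fits are flagged rather than hidden: complete
separation (all events in one group) reports an unbounded CI, and
non-convergence excludes the gene with a log entry.

A multivariable helper applies the conventional two-stage selection:
covariates with univariate Wald p < 0.15 enter a joint Cox fit; exact
duplicates or an ill-conditioned standardized design raise an error naming
the offending pair.

## The index

The index multiplies the stored log2 expression values of the harmful genes
and divides by the product over favorable genes. The products are taken on
the log2 scale *as given* — the definition this package implements applies
the ratio directly to expression values, and all inputs here are log2 — which
makes the score unit-sensitive: it is only meaningful on positive,
consistently scaled values, so any non-positive factor raises an error naming
the gene and sample. Swapping the two sets inverts the index per sample;
adding a gene to the numerator multiplies each sample's index by that gene's
value; rescaling one gene by c > 0 scales the index by c without changing the
median-split grouping.

Stratification is at the median index (ties to low). The survival association
is reported three ways: log-rank on the groups, Cox on the group indicator,
and Cox on the standardized continuous index, whose HR reads per SD — the
continuous form is the default headline number because a ratio-scale score
has no natural unit.

## Group comparison and the transcriptome shift

Differential expression between the index groups uses Welch's unequal-
variance t-test per gene (a pooled-variance switch exists; Welch is the safer
default when group variances differ), with log2FC oriented high − low. The
DEG rule is the joint condition |log2FC| > 1 AND p < 0.05 on raw p-values; a
BH-FDR column is available but off by default, and the raw-p convention is a
documented caveat, not an endorsement. Top tables rank significant genes by
|log2FC|, breaking ties by smaller p then gene name.

The transcriptome-shift question — does the index-high group sit globally
lower in RNA levels? — is posed as a location test of the DEG fold changes
against zero, one-sided toward negative: a Wilcoxon signed-rank by default,
with a sign test and a mirrored two-sample Kolmogorov–Smirnov variant as
alternatives since no single test is canonical for this figure style.
Empirical-CDF points are emitted for cumulative-distribution plots.

## Panel structure

Gene–gene structure is summarized by pairwise Pearson correlation (constant
genes are reported as undefined, never coerced to zero) and by average-
linkage agglomerative clustering on cosine distance (1 − cosine similarity)
of the raw gene vectors, exported as a Newick dendrogram. Average linkage is
the choice where only the similarity, not the linkage, is conventionally
reported. Samples are soft-partitioned by fuzzy c-means (Bezdek alternating
optimization; implemented in-package) on the z-scored panel — standardization
stops high-variance genes from dominating the distance — with c = 2 clusters,
fuzzifier m = 2.0 (the standard default), random membership initialization
from a seed, and convergence when the largest membership change drops below
1e-6 (cap 300 sweeps). Cluster labels are arbitrary, so agreement statistics
first match labels to a reference by Hungarian assignment on the contingency
table.

## Over-representation

Enrichment of a DEG list in GMT gene sets is the one-sided hypergeometric
upper tail P[X ≥ k] with BH FDR across tested sets. The universe is all genes
on the matrix after probe collapse — the standard conservative choice when
the original tool's universe is unknowable. Sets with no universe member are
skipped; DEGs outside the universe are dropped with a warning.

## Synthetic cohorts

The generator emulates a bulk-microarray survival cohort at the level the
pipeline consumes. Expression: each gene is Gaussian with baseline mean 8.0
log2 units and SD 1.0 (typical RMA intensities); genes in the same block
share a latent Gaussian factor with loading √r, giving pairwise correlation r
(for a 2-gene block, ±√|r| loadings allow negative r; a k > 2 equicorrelated
block requires r > −1/(k−1) and is rejected otherwise). Survival: exponential
times with hazard `baseline_hazard · exp(Σ_g β_g z_ig)` where z is the
standardized expression of signature gene g — so β is the log HR per SD and
the exponential baseline is the simplest proportional-hazards-consistent
choice. Censoring combines an independent exponential whose rate is solved by
root-finding so the expected censored fraction matches `censoring_rate`
(default 0.30), and an administrative cutoff at 120 months. Everything is
reproducible from one integer seed.

The default `paperlike_config` is the cohort the pipeline is designed for:
123 samples, an 8-gene panel over 500 null background genes. Three strongly
harmful genes (β = 0.30, 0.30, 0.45) and one moderate (β = 0.15) share a
correlation block at r = 0.45; one strongly favorable gene (β = −0.55) is
correlated at r = 0.46 with a null panel gene; two near-null singletons
(β = 0.10, 0.05) complete the panel. Because block correlation inflates each
gene's *marginal* effect (β_g plus r times the other block betas), these
direct betas put the median-split HRs of the strong genes near 2–2.5
(favorable near 0.4–0.6) and make about five of the eight genes significant
at n = 123 — the regime the pipeline targets.

What the generator does not emulate: probe-level structure, heavy-tailed or
skewed intensity distributions, sample-level batch effects, non-proportional
hazards, informative censoring, or any coupling between background genes and
the index groups. Passing tests therefore validate the estimators and the
pipeline logic under the stated model, not robustness to those violations.

## Numerical choices and degenerate inputs

- Ties at any data-driven cutoff (dichotomization, index stratification) go
  to the low group, making splits deterministic.
- Constant vectors cannot be split or standardized and raise errors; constant
  genes in correlation output are NaN-flagged.
- TSV round trips are bit-identical: values are written with 17 significant
  digits and parsed with correctly-rounded float conversion (the fast pandas
  parser can be off by one ulp).
- Cosine distances are clipped at 0 against floating-point noise; correlation
  matrices are symmetrized and clipped to [−1, 1] before reporting.
- Fuzzy c-means guards zero distances with a 1e-12 floor so a sample exactly
  on a centroid gets full membership there.
- The log-rank test requires two non-empty groups and ≥ 1 event; Cox fits
  require ≥ 2 events and a non-constant covariate; the shift test requires
  ≥ 5 fold changes.

## Validation problem sizes

The test suite works at sizes chosen to make each check sharp but quick:
oracle equivalence of the log-rank statistic on 200 random datasets of n ≤ 30
against an independently coded O−E/V sum (|Δ| < 1e-8); exhaustive
hypergeometric enumeration for every universe of ≤ 12 genes; Cox consistency
at n = 2000 (true HR 2, estimate within [1.8, 2.2]) and null calibration over
200 cohorts of n = 100 (binomial 99% bounds on the p < 0.05 rate); signature
recovery over 100 study-like cohorts of 123 samples; and shift-test null
uniformity over 500 replicates (KS p > 0.01). `scripts/acceptance.py` re-runs
the same computations from scratch and writes the resulting numbers as JSON.

## Known limitations

- The index is scale-dependent by construction; comparing index values across
  platforms or normalizations is not meaningful without re-deriving the cut.
- Raw-p DEG calling inflates false positives at transcriptome scale; switch
  on the FDR column for any discovery-oriented use.
- The two-stage multivariable selection inherits the usual criticisms of
  p-value-gated model building; it is provided for parity with common
  practice, not as a recommendation.
- Fuzzy c-means finds a local optimum; different seeds can converge to
  different soft partitions when clusters are not well separated.
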