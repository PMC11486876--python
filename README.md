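# lsmsurv

Gene-signature survival analysis for expression cohorts, built around a
multiplicative prognostic index.

Many cancer cohorts — the motivating case is mantle cell lymphoma profiled on
Affymetrix arrays — come as a log2 expression matrix plus overall-survival
follow-up. `lsmsurv` turns a small gene panel (such as the LSM1–LSM8 family of
Sm-like RNA-decay genes) into a prognostic score and characterizes the
resulting patient strata. It is a library first (`import lsmsurv`), with an
`examples/` directory of narrative scripts and a thin `lsmsurv` CLI for batch
runs.

## The model

For each panel gene, expression is median-split and tested against survival
(Kaplan–Meier, log-rank, and a Cox proportional-hazards fit with Efron tie
handling and Wald 95% CIs). A gene with hazard ratio HR > 1 is *harmful*,
HR < 1 *favorable*. Genes passing the screen (log-rank p < α, or an explicit
override list) form two sets, and each sample *j* gets the index

```
index_j = ∏_{g ∈ harmful} x_gj / ∏_{f ∈ favorable} x_fj
```

where `x` are the stored log2 expression values. Samples are stratified at the
median index; the high/low groups are then compared by log-rank and Cox
(group indicator and standardized continuous index), per-gene Welch t-tests
with the DEG rule |log2FC| > 1 and p < 0.05, a one-sided Wilcoxon signed-rank
test for a global downward shift of DEG fold changes, Pearson correlation and
cosine-distance clustering of the panel, fuzzy c-means partitioning of the
samples, and hypergeometric over-representation of the DEGs in GMT gene sets
with BH FDR.

A synthetic-data generator (`lsmsurv.simulate`) reproduces the statistical
structure this pipeline assumes — latent-factor gene–gene correlation blocks
and exponential proportional-hazards survival driven by standardized
signature expression, with independent plus administrative censoring — so the
entire analysis is testable without any accession download.

## Worked example

```python
import lsmsurv as L

dataset = L.simulate(L.paperlike_config(seed=1))           # 123 samples
panel = [f"LSM{i}" for i in range(1, 9)]
screen = L.screen_genes(dataset.expression, dataset.survival, panel)

gs = L.GeneSets(harmful=("LSM1", "LSM2", "LSM4"), favorable=("LSM8",))
assign = L.stratify_index(L.compute_index(dataset.expression, gs))
ev = L.evaluate_index(assign, dataset.survival)
```

With seed 1 this prints (see `examples/01_screen_panel.py` and
`examples/02_build_index.py`):

```
5 of 8 panel genes are survival-associated (p < 0.05)
log-rank: chi2 = 39.15, p = 3.93e-10
index-high vs index-low HR = 4.39 (95% CI 2.67-7.24)
continuous index HR per SD = 2.74
```

Five of the eight planted signature genes reach significance (the three
strongly harmful genes with HR ≈ 2–2.5, the favorable gene at HR ≈ 0.39, plus
one moderate gene), and the index built from them separates the cohort into a
high-risk and a low-risk half — the index-high group dies roughly four times
faster. The other scripts in `examples/` walk through differential
expression, panel structure/clustering, enrichment, and the end-to-end
pipeline with its TSV artifact directory and hashed manifest.

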