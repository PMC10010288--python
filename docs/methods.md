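# Methods

This note documents the models and procedures `csgtools` implements, the
defaults it ships, and the design decisions taken where the procedure was
genuinely open.

## The CSG classification model

The package classifies tumors into four cGAS-STING groups (CSG1–4) from
bulk expression of an eight-gene signature split into an *activator* set
(STING1, CGAS, IFI16, ATM — pathway sensing/initiation) and a *response*
set (CCL5, CXCL9, CXCL10, CXCL11 — downstream chemokine output). The
intended biology: CSG1 = functional but inactive pathway (activators
relatively up, responders down); CSG2 = non-functional pathway with
non-canonical NFκB output (both sets low, responders relatively up);
CSG3 = fully active pathway (everything high, CGAS–STING1 positively
correlated); CSG4 = aberrant activation (activators high, responders low,
CGAS–STING1 negatively correlated).

### Signature selection

From a 20-gene candidate list, the signature keeps genes with inter-sample
SD > 1 **and** per-gene mean above a cohort reference, both on the
log2(TPM+1) scale. "Cohort reference" is read as the median of per-gene
mean expression over all genes in the matrix (default); the alternative
reading — the median of all matrix values — is available via
`cohort_median_of="all_values"`. SD uses the n−1 denominator. The filter is
scale-sensitive, so linear-scale input is rejected rather than silently
transformed. The packaged candidate list contains the eight signature genes
plus twelve pathway-adjacent placeholders and is replaceable
(`--candidates`).

### Discovery

1. **z-scoring.** Per-gene centre/SD fitted on the discovery cohort
   (full-cohort, not per-cancer-type). The fitted parameters are stored in
   the model for the single-sample path.
2. **Embedding.** UMAP to 2-D with `n_neighbours=30`, `min_dist=0.01`,
   `learning_rate=0.01`, fixed seed. `spread` defaults to the umap-learn
   default of 1.0 rather than 0.05: `spread` (with `min_dist`) shapes the
   low-dimensional similarity kernel, and a kernel scale two orders of
   magnitude below typical embedding distances suppresses repulsion so
   strongly that adjacent clusters collapse. Measured on the default
   synthetic cohort, spread 0.05 gives a true-label silhouette of ~0.3 and
   k-means(4) ARI of ~0.6 (the two low-expression groups merge); spread 1.0
   with everything else unchanged gives silhouette ~0.75 and ARI ~0.95.
   `EmbeddingConfig.published()` provides the verbatim combination for
   comparison work.
3. **K selection.** k-means (10 restarts, best inertia, Euclidean on the
   2-D embedding) for K = 1–8, K chosen at the elbow of the within-cluster
   sum-of-squares (WSS) curve. The default elbow detector is **Kneedle on
   log(WSS)**: the K with maximum distance below the chord joining the
   log-curve's endpoints. The log scale makes the rule scale-invariant and
   sensitive to relative drops; on measured curves the K=3→4 transition
   halves-to-thirds the WSS while K≥5 improves it by only ~15%, yet
   raw-scale rules (maximum second forward difference, raw Kneedle) are
   dominated by the enormous absolute drops at K=2–3 and mis-locate the
   elbow even on embeddings with four cleanly separated clusters. Both
   raw-scale rules remain available via `select_k(method=...)`.
4. **Semantic mapping.** Clustering yields anonymous ids; the CSG names are
   assigned from each cluster's mean activator (A) and response (R)
   z-scores: CSG3 = argmax(A+R), then CSG4 = argmax(A−R) among the rest,
   then CSG2 = argmax(R−A), and the last cluster is CSG1. Ties break toward
   the lower cluster id and are logged. This ranking is the package's
   operationalisation of the qualitative group definitions above.
5. **Recapture forest.** A 200-tree random forest trained on an 80%
   stratified split of the z-scored 8-gene matrix to predict the cluster
   labels; OOB error and held-out accuracy are stored in the model.
   Remaining forest hyperparameters are scikit-learn defaults (√p features
   per split, unlimited depth) and travel with the serialized model.

### Classification of new data

Cohorts of ≥ 30 samples are re-normalised by their own per-gene centre/SD
(matching how an independent test cohort is normalised by its own
statistics); smaller inputs — down to a single sample — fall back to the
stored training parameters. The threshold of 30 is a pragmatic cut-off
below which cohort-level SD estimates are too unstable; both paths can be
forced via `classify(..., renormalize=True/False)`. Missing panel genes are
a hard error — no silent imputation.

## Summary statistics

* **wGII** — per autosome, the fraction of covered bases whose total copy
  number (major+minor) differs from the sample's ploidy rounded half-up;
  averaged with equal weight over the 22 autosomes (built-in GRCh38
  lengths). Rounding the ploidy makes balanced whole-genome-doubled
  genomes score 0. Sex chromosomes are read but excluded. Chromosomes
  covered below 90% of their length trigger a warning and are scored over
  covered bases; entirely missing chromosomes are excluded from the mean.
  Total copy number (rather than major allele) against rounded ploidy is
  the documented convention choice.
* **TMB** — nonsynonymous mutation count divided by the capture size,
  default 38 Mb (a typical exome capture) when none is supplied.
* **NFκB subunit ratio** — log2((NFKB1+1)/(NFKB2+1)) on the linear scale
  (+1 tolerates zeros); on log2(TPM+1) input this is the difference of the
  stored values. Low values indicate NFκB2-dominant, non-canonical
  signalling.
* **TIL score** — Danaher-style marker-set scoring: per cell type the mean
  log2(TPM+1) of present markers; the TIL score averages the per-cell-type
  scores (pooling all markers instead is available behind `pool=True`).
  The shipped catalog is a small editable stand-in; curated marker lists
  should replace it for real analyses.
* **Per-group statistics** — CGAS–STING1 Pearson r per group (groups with
  < 3 samples report NA) and per-group TP53 loss-of-function fractions
  (a sample counts once regardless of duplicate records).

## Stratification and outcome models

Median splits of wGII and neoantigen burden use cohort-wide medians with
"high" inclusive of the median (avoids empty high groups in small
cohorts); the medians are recorded in the output. Responders are CR/PR.
The quadrant analysis compares responders in the double-high quadrant
against all other samples within a CSG using a two-sided Fisher exact
test (χ² behind a flag). Survival uses Kaplan–Meier curves with the
multivariate log-rank test, and Cox proportional-hazards fits with
Efron tie handling, CSG1 as the reference level, continuous covariates on
their natural scale (scales recorded in the result), and optional product
interaction terms — in particular CSG3 × wGII × neoantigen burden.
Constant covariates, exact collinearity, designs with fewer events than
terms, and non-convergence raise errors rather than returning silent
coefficients. The per-cancer-type meta-analysis fits CSG-vs-CSG1 models
within each type and pools log-HRs by fixed-effect inverse variance
(pooled variance 1/Σ(1/SEᵢ²)); unfittable types are excluded with a
warning and reported.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes and
provides ground truth for recovery tests. Defaults (all overridable):

* **Archetypes** (activator, response z-means): CSG1 (−0.5, −1.0), CSG2
  (−1.0, −0.3), CSG3 (+1.0, +1.0), CSG4 (+0.8, −0.5); CGAS–STING1
  correlation +0.8 in CSG3, −0.6 in CSG4, 0 elsewhere; NFκB log-ratio
  means 0.5/−1.0/1.0/1.0 (lowest in CSG2). These reproduce the qualitative
  group orderings, not any measured effect sizes — within-group variances
  and magnitudes are not reported for the real cohorts, so magnitudes here
  are design parameters.
* **Expression.** 200 samples/group; latent z-values (archetype mean +
  N(0, noise_sd), noise_sd = 0.5) placed affinely on the log2 scale
  (base 6.0, scale 1.5) so the signature genes clear both selection
  filters by construction; NFKB1/2, TP53, 14 TIL markers (elevated most in
  CSG3, then CSG4) and 1,000 uniform-mean background genes complete the
  matrix. Values are clipped at 0.
* **Copy number.** Each autosome is tiled gap- and overlap-free with an
  aberrant prefix (total CN 3 vs diploid) covering a genome fraction drawn
  from the regime range — high (0.4–0.7) vs low (0.0–0.2) — so measured
  wGII equals the drawn fraction up to base rounding and the median split
  recovers the true regime exactly.
* **Mutations.** Poisson counts (mean 60 high-neoantigen regime / 15 low,
  over a 38 Mb capture ≈ TMB 1.6 vs 0.4/Mb, with 75% nonsynonymous);
  TP53 LOF carried by 25/30/20/60% of CSG1–4 samples (highest in CSG4).
* **Clinical.** Response ~ Bernoulli(logit = −2.0 + 0.4·CSG3 +
  0.2·highwGII + 0.6·highNeo + 0.6·triple-interaction), giving ~12%
  baseline and ~45% triple-high response rates; survival exponential with
  baseline hazard 1/12 per month and log-HRs (−0.3, −0.2, −0.3) plus a
  −1.5 triple interaction; 25% uniform censoring; neoantigen burdens
  gamma-distributed with regime means 2.8 vs 1.2.

A single `seed` determines every table via per-operation independent
random streams, so outputs are byte-identical across runs and insensitive
to call order. What the generator does **not** emulate: cancer-type
batch structure in expression, correlated noise between genes outside the
CGAS–STING1 pair, focal copy-number architecture, purity effects on copy
number, non-proportional hazards, or covariate-dependent censoring.
Passing tests therefore demonstrate correctness of the procedures and
recoverability of configured effects, not performance on real tumors.

## Problem sizes and numerical choices

Tests and the acceptance script run discovery cohorts of 800 samples
(200/group), 20 replicate seeds for elbow stability, 50 replicates for
interaction recovery, and 100 random profiles for the wGII oracle — sizes
at which every Monte-Carlo bound tested has comfortable margin while the
whole suite completes in a few minutes. wGII oracle agreement is asserted
to 1e−9; k-means uses 10 restarts; UMAP, k-means, splits and forests are
all explicitly seeded. Degenerate inputs (zero-SD genes, constant
covariates, all-censored groups, empty marker sets, ties in the semantic
mapping) raise or warn explicitly rather than propagating silently.

## Known limitations

* The CSG semantic mapping assumes exactly four clusters; discovery
  refuses to proceed if the elbow lands elsewhere rather than guessing.
* The published embedding `spread`/`learning_rate` combination is replaced
  by a working default (see above); results on real cohorts may therefore
  differ in embedding geometry from the original, though the cluster
  semantics are defined by the A/R ranking, not by coordinates.
* Real-cohort headline numbers (response rates by CSG, median survivals,
  printed hazard ratios) require the original TCGA and immunotherapy
  cohorts and are out of scope; the package reproduces the procedures and
  recovers configured effects from synthetic data.
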