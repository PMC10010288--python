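# csgtools

Classification of tumors by cGAS-STING pathway activation state from bulk
RNA-seq, with the genomic and immune summary statistics and the
immunotherapy stratification analyses built on top of it.

The cGAS-STING pathway senses cytosolic DNA — a common by-product of
chromosomal instability (CIN) — and, when functional, drives an interferon
and chemokine response that recruits immune cells into the tumor. Tumors
differ in whether this pathway is intact, silent, or aberrantly activated,
and that difference modulates both prognosis and the benefit of checkpoint
immunotherapy. `csgtools` implements an expression-based classifier that
assigns each tumor to one of four **cGAS-STING groups**:

| group | activator genes | response genes | interpretation |
|-------|----------------|----------------|----------------|
| CSG1  | moderate-low   | low            | functional, not activated |
| CSG2  | low            | moderate-low   | non-functional, non-canonical NFκB output |
| CSG3  | high           | high           | fully active pathway |
| CSG4  | high           | low            | activated but failing to mount the IFN response |

The signature is eight genes: an *activator* set A = {STING1, CGAS,
IFI16, ATM} and a *response* set R = {CCL5, CXCL9, CXCL10, CXCL11},
selected from a 20-gene candidate panel by requiring inter-sample SD > 1
and mean expression above the cohort median (log2(TPM+1) scale).
Discovery z-scores the signature per gene, embeds samples into 2-D with
UMAP (n_neighbours = 30, min_dist = 0.01), scans k-means over K = 1–8,
picks K at the elbow of the within-cluster sum-of-squares curve, names
the clusters by ranking their mean activator/response z-scores (CSG3 =
argmax A+R; CSG4 = argmax A−R among the rest; CSG2 = argmax R−A; CSG1 the
last), and trains a 200-tree random forest on an 80/20 stratified split
to recapture the labels — making the grouping applicable to single
samples.

Around the classifier the package provides:

* **wGII** — weighted genome integrity index: the per-autosome fraction of
  the genome whose total copy number deviates from the rounded sample
  ploidy, averaged equally over the 22 autosomes (a CIN measure in [0,1]);
* **TMB** — nonsynonymous mutations per megabase;
* **TIL score** — Danaher-style immune marker-set scoring;
* **NFκB1/NFκB2 log-ratio**, per-group CGAS–STING1 correlation, and
  per-group TP53 loss-of-function fractions;
* **stratification analyses** — cohort-median splits of wGII and
  neoantigen burden, quadrant response tables with Fisher exact tests,
  Kaplan–Meier / log-rank comparisons, multivariable Cox models with the
  CSG3 × wGII × neoantigen interaction, and a per-cancer-type
  inverse-variance meta-analysis against the CSG1 reference;
* a **synthetic cohort generator** producing linked expression,
  copy-number, mutation and clinical tables with known ground truth, used
  throughout the test suite.

It is aimed at computational oncology groups who want to apply or probe
the CSG grouping on their own expression cohorts, or to benchmark
CIN/immune-interaction analyses against a generator with known truth.

## Worked example

```python
import dataclasses
from csgtools import SimConfig, simulate_cohort, discover
from csgtools.panel import select_signature_genes
from csgtools.metrics import sample_metrics
from csgtools.analysis import (SurvivalModelSpec, cox_model, km_compare,
                               stratify)

cohort = simulate_cohort(dataclasses.replace(SimConfig(), seed=42))

panel = select_signature_genes(cohort.expr)
print(panel.selected)
# ['STING1', 'CGAS', 'IFI16', 'ATM', 'CCL5', 'CXCL9', 'CXCL10', 'CXCL11']

model, labels = discover(cohort.expr, panel=panel, seed=42)
print(model.k, f"{100*model.oob_error:.2f}%", f"{100*model.test_accuracy:.1f}%")
# 4 0.94% 99.4%
```

The elbow lands at K = 4 and the recapture forest misclassifies 0.94% of
out-of-bag training samples (98.2% of samples get their true generator
label back). Summary metrics recover the configured group structure —
the NFκB log-ratio is lowest in CSG2, flagging non-canonical signalling:

```python
mets = sample_metrics(cohort.profiles, cohort.mutations, cohort.expr, csg=labels)
print(mets.groupby("csg")[["wgii", "tmb", "nfkb_log_ratio"]].mean().round(3))
#        wgii    tmb  nfkb_log_ratio
# csg
# CSG1  0.327  0.710           0.447
# CSG2  0.316  0.775          -0.940
# CSG3  0.286  0.715           0.982
# CSG4  0.306  0.733           0.990
```

Stratifying on the cohort medians of wGII and neoantigen burden and
fitting survival models shows the configured benefit concentrated in
CSG3 tumors with both high CIN and high neoantigen burden:

```python
strat = stratify(cohort.clinical, mets, labels)
km = km_compare(strat, "csg")
print(km.medians.round(1), f"p = {km.logrank_p:.2g}")
# CSG1 11.5, CSG2 13.6, CSG3 20.0, CSG4 12.4 months; log-rank p = 9.8e-08

res = cox_model(strat, SurvivalModelSpec(
    covariates=["csg", "wgii_high", "neo_high"],
    interaction_terms=[("csg3", "wgii_high", "neo_high")]))
print(res.summary.loc["csg3_x_wgii_high_x_neo_high"].round(3))
# hr 0.581, 95% CI (0.377, 0.895), p = 0.014
```

The three-way interaction hazard ratio of 0.58 (p = 0.014) means the
double-high CSG3 subgroup does better than its main effects predict —
median overall survival 40.4 months versus 13.2 for everyone else in this
simulation. (The fitted HR is attenuated relative to the generator's
exp(−1.5) ≈ 0.22 because median splits of the overlapping neoantigen
distributions misclassify some samples' regimes — as they would in real
data.)

The same steps are available from the shell:

```
csgtools simulate --outdir cohort/ --seed 42
csgtools discover --expr cohort/expression.tsv --out model.joblib --labels-out labels.tsv
csgtools classify --model model.joblib --expr cohort/expression.tsv --out calls.tsv
csgtools metrics  --segments cohort/segments.seg --mutations cohort/mutations.tsv \
                  --expr cohort/expression.tsv --out metrics.tsv
csgtools stratify --clinical cohort/clinical.tsv --metrics metrics.tsv \
                  --labels labels.tsv --out strat.tsv
```

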