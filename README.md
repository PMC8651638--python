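# endopheno

Discovery and validation of whole-blood transcriptomic **endophenotypes** in
idiopathic/heritable pulmonary arterial hypertension (I/HPAH).

I/HPAH is diagnosed by right-heart catheterisation and exclusion — a single
clinical label covering a biologically heterogeneous population with very
different outcomes.  This package implements an unsupervised route to
molecular subgroups from whole-blood RNA-seq, and the downstream validation
that makes such subgroups credible: gene signatures, clinical-feature
signatures that transfer to cohorts without RNA, survival separation, and
qPCR confirmation.  Because the motivating cohort data are under restricted
access, the package includes a synthetic-cohort generator that plants the
assumed statistical structure (marker-gene blocks, subgroup-linked clinical
shifts and hazards, a prognosis-associated genotype), so the entire pipeline
is runnable and testable end to end from nothing but a seed.

## Method

Given a gene × sample TPM matrix **X**:

1. **Preprocess** — keep genes with TPM > 2 in ≥ 95% of samples, remove
   chrX/chrY genes (sex is the dominant nuisance axis in whole blood),
   transform `x ↦ asinh(x)`.
2. **Discover** — rank genes by variance; for candidate set sizes, cluster
   patients by spectral clustering on the RBF affinity
   `A_ij = exp(−σ‖x_i − x_j‖²)` (symmetric normalised Laplacian
   `L_sym = I − D^{−1/2} A D^{−1/2}`, top-k eigenvector embedding, k-means);
   choose the gene-set size maximising bootstrap cluster stability (mean
   best-match Jaccard over resampled patients); choose k by majority vote of
   internal validity indexes (silhouette, Calinski–Harabasz, Davies–Bouldin,
   Dunn, connectivity, WB-ratio, PBM, C-index).  Algorithm choice itself is
   justified by partitional consistency — mean pairwise adjusted Rand index
   (ARI) across each algorithm's variations.
3. **Gene signatures** — one-vs-rest LASSO (L1 logistic) per subgroup with
   cross-validated penalty (1-SE rule); top-5% coefficients highlighted;
   Bonferroni-adjusted Welch tests on raw-scale log2 fold changes.
4. **Clinical signatures & transfer** — drop features > 5% missing, impute
   the rest by chained equations (predictive mean matching for numerics),
   ensemble feature selection (effect size + L1 + permutation importance),
   signature-size search s = 1..20 over SVM/RF/LR/kNN, pool per-subgroup
   signatures into one composite multi-class classifier, and classify an
   independent cohort that has no transcriptome.
5. **Validate** — Kaplan–Meier curves and log-rank tests per (predicted)
   subgroup, Cox proportional hazards with covariates (Efron ties),
   two-proportion and Fisher tests for categorical associations, a
   gene–clinical Spearman network (|ρ| ≥ 0.25, p < 1.11×10⁻⁵), and ΔΔCt
   qPCR fold ratios (RQ = 2^(−ΔΔCt)) against a reference assay.

Full model details, parameter defaults and design rationale are in
[docs/methods.md](docs/methods.md).

## Worked example

The `analysis/` drivers run the whole study on a synthetic cohort
(n = 330 discovery, n = 197 validation, 1000 genes, seed 1):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_preprocess.py
python analysis/03_discover_subgroups.py --seed 1
python analysis/04_gene_signatures.py --seed 1
python analysis/05_clinical_transfer.py --seed 1
python analysis/06_survival_validation.py
python analysis/07_network_qpcr.py --seed 1
```

Output of the discovery step:

```
most consistent algorithm: spectral
index votes: {'c_index': 3, 'calinski_harabasz': 3, 'connectivity': 2, 'davies_bouldin': 4,
              'dunn': 3, 'pbm': 2, 'silhouette': 3, 'wb_ratio': 8}
voted number of subgroups: k = 3
subgroup sizes: {1: 129, 2: 112, 3: 89}
ARI against planted labels: 1.000
```

Five of eight indexes vote k = 3; the spectral partition recovers the three
planted subgroups exactly (ARI 1.0), sized 129/112/89.  Gene signatures then
isolate the planted marker blocks — the poor subgroup's top coefficients are
all ALAS2-like genes, the good subgroup's are NOG-like — and the
immunoglobulin block shows the low/intermediate/high ordering (block medians
9.1 / 24.6 / 66.2 TPM for poor/moderate/good, trend p ≈ 2×10⁻³¹).
Survival and transfer validation:

```
discovery cohort (time from sampling):
  subgroup 1: 5-year survival 50.6%      # planted 53%
  subgroup 2: 5-year survival 76.6%      # planted 78%
  subgroup 3: 5-year survival 74.0%
  log-rank chi2 = 28.5, p = 6.64e-07
Cox model:  poor_subgroup HR 2.30 [1.54, 3.43]

composite signature (6 features): ['age_diagnosis', 'bmi', 'nt_probnp',
                                   'creatinine', 'crp', 'six_mwd']
balanced accuracy vs planted validation labels: 0.880
validation cohort (predicted subgroups, time from diagnosis):
  subgroup 1: 5-year survival 54.6%
  subgroup 2: 5-year survival 73.6%
  log-rank chi2 = 20.3, p = 3.95e-05
```

The clinical classifier, trained only on discovery-cohort clinical features,
stratifies the independent cohort into subgroups whose survival curves
reproduce the planted hazard ordering.

A single `endopheno` CLI wraps the same stages
(`endopheno simulate | preprocess | discover | survive | qpcr | run`);
`endopheno run --seed N --out dir/` executes the full pipeline and writes a
manifest (config, input hashes, per-stage seeds) from which the run is
byte-for-byte reproducible.

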