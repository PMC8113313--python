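# radphen

Radiomic tumor phenotypes and their added prognostic value for EGFR-mutant
advanced NSCLC treated with tyrosine kinase inhibitors.

Not every patient with a therapeutically targetable *EGFR* mutation responds
to targeted therapy, and neither ctDNA liquid-biopsy measures nor clinical
covariates fully explain the difference. `radphen` implements an analysis
that asks whether unsupervised **radiomic phenotypes** — tumor subgroups
defined purely by patterns in CT texture features — add prognostic value on
top of clinical and ctDNA variables for progression-free and overall
survival. It is written for quantitative-imaging and biostatistics
researchers who want the whole chain, from feature matrix to model
comparison, as tested, seedable code.

## The method

**Two-level consensus clustering with PC signatures.** Given a tumors ×
features matrix of radiomic descriptors (z-scored per feature), features are
compared with the correlation distance

> d(f, g) = 1 − r²(f, g)

so strongly covarying features are close regardless of sign. Features are
grouped by complete-linkage (maximum-distance) agglomerative clustering, and
the number of feature clusters k is chosen by consensus clustering: repeated
subsampling, reclustering, and a consensus matrix M whose entry (i, j) is
the fraction of co-sampled runs in which i and j co-cluster. k is the
smallest value for which the relative change in the area under the CDF of
consensus values, (A(k+1) − A(k))/A(k), falls below 10%. Each feature
cluster is summarized by the first principal component of its submatrix (a
*derived feature signature*), and the same consensus machinery applied to
tumors over the signature matrix yields the radiomic phenotypes, whose
two-vs-one-cluster significance is tested with a SigClust Monte-Carlo test.

**Survival modeling.** Phenotype (2 vs 1), clinical covariates (age,
smoking, ECOG grade, line of therapy), and ctDNA mutation count enter Cox
proportional-hazards models (Newton–Raphson on the partial likelihood,
Efron tie handling). Covariates passing a univariable screen (p ≤ 0.2;
mutation count always kept) form a multivariable model fitted with and
without phenotype; the nested pair is compared by likelihood-ratio test, and
discrimination is measured with Uno's IPCW concordance statistic with
horizon τ = the longest event time. Kaplan–Meier curves split at the median
prognostic score x'β̂ give the log-rank view of the combined model.

**Synthetic cohorts.** Because the 40-patient study data are not deposited,
`radphen.synthetic_cohort` generates cohorts with planted ground truth:
latent-factor feature clusters with exact expected within-cluster
correlation ρ, phenotypes separated by a configurable shift on a subset of
clusters, covariate marginals matching the published cohort, exponential
event times under a proportional-hazards model, and independent censoring —
plus 3D phantoms (image + mask) for the feature-extraction path. Every
stage of the pipeline has a parameter-recovery or calibration test against
this generator.

## Worked example

```python
from radphen import RunConfig, run_analysis
from radphen.synthetic_cohort import CohortConfig

config = RunConfig(
    simulate=CohortConfig(seed=1),      # 40 tumors x 429 radiomic features
    feature_k_range=(2, 40),
    n_resamples=500,
    n_boot=500,
    sigclust_n_sim=1000,
    seed=1,
)
report = run_analysis(config)

phen = report["phenotyping"]
print(f"derived feature clusters (k): {phen['selected_feature_k']}")
print(f"phenotypes: {phen['selected_phenotype_k']}  sizes: {phen['phenotype_sizes']}")
print(f"SigClust p (2 clusters vs 1): {phen['sigclust_p']:.4g}")
for name, ep in report["endpoints"].items():
    with_ = ep["models"]["with_phenotype"]
    without = ep["models"]["without_phenotype"]
    print(f"{name}: c = {without['c_statistic']['c']:.2f} -> {with_['c_statistic']['c']:.2f} "
          f"with phenotype; LRT p = {with_['lrt_vs_without_phenotype']['p']:.3g}; "
          f"median-score split log-rank p = {ep['median_score_split']['logrank_p']:.3g}")
```

Output:

```
derived feature clusters (k): 3
phenotypes: 2  sizes: {1: 21, 2: 19}
SigClust p (2 clusters vs 1): 0.000999
PFS: c = 0.63 -> 0.78 with phenotype; LRT p = 2.67e-05; median-score split log-rank p = 0.000698
OS: c = 0.58 -> 0.69 with phenotype; LRT p = 0.0124; median-score split log-rank p = 0.00858
```

Reading the numbers: on this simulated cohort the consensus CDF rule keeps 3
derived feature signatures and splits the 40 tumors into phenotypes of 21
and 19 (a split far tighter than a single Gaussian explains, SigClust
p ≈ 0.001). Adding phenotype to the clinical + ctDNA Cox model raises the
PFS c-statistic from 0.63 to 0.78 and fits significantly better by the
nested LRT — the phenotypes carry prognostic signal beyond the other
covariates, which is exactly what the generator planted.

The same run is available from the shell:

```bash
radphen simulate --config cfg.ini --out cohort/ --seed 1
radphen run --config cfg.ini --out results/ --seed 1 --format markdown --plot
```

with `cfg.ini` holding `[simulate]`, `[phenotyping]` and `[survival]`
sections (flags override file values). `run` writes `report.json` (plus tsv
or markdown renderings), signatures, phenotype labels, the consensus matrix,
and — with `--plot` — consensus-CDF and Kaplan–Meier figures. Undefined
survival medians are reported as `NR` (not reached).

## Feature extraction from images

`radphen.radiomic_features` extracts a documented subset of the classical
descriptor families from a 3D image + mask (NIfTI or arrays): first-order
intensity statistics, 3D shape, GLCM / GLRLM / GLSZM / GLDM / NGTDM texture
families (fixed-bin-count discretization, 13-direction averaging,
26-connectivity), and Laplacian-of-Gaussian and Haar-wavelet filtered
variants. Phantom volumes from the synthetic module exercise this path; the
output table feeds straight into the phenotyping pipeline.

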