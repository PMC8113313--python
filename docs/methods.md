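# Methods

This note documents the models and procedures `radphen` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Feature-level clustering and signatures

Features are z-scored per column with the sample standard deviation
(ddof = 1); constant columns carry no between-tumor information and are
dropped with a warning that propagates into the run report. The feature
distance is d = 1 − r², r the Pearson correlation across tumors. This
treats anti-correlated features as close (they carry the same information up
to sign) and is symmetric with zero diagonal, but it is **not a metric** —
the triangle inequality can fail — so no step assumes metricity; clustering
uses complete linkage, which needs only pairwise dissimilarities.

Consensus clustering follows the resampling construction: `n_resamples`
(default 500) subsamples of a fraction `subsample_frac` (default 0.8) of the
items are drawn without replacement; each subsample is clustered by
complete-linkage agglomeration of the restricted distance matrix, one
linkage tree serving every k in the range; the consensus matrix entry
M(i, j) is the number of co-clusterings divided by the number of
co-samplings (0 for never co-sampled pairs, 1 on the diagonal). The CDF of
the upper-triangle consensus entries is evaluated on a 100-point grid over
[0, 1] and A(k) is the area under it. k is selected as the smallest value
with (A(k+1) − A(k))/A(k) below the 10% cutoff; if no k qualifies, the
largest k in range is returned with a warning. A data-perturbation variant
(resampling tumors and re-estimating the correlation distance per resample)
was evaluated during development and recovered planted cluster counts at the
same rate, so the simpler frozen-distance scheme is used.

Each feature cluster is summarized by the first principal component of its
tumors × cluster-features submatrix (SVD of the column-centered block).
PC sign is arbitrary, so each signature is oriented to correlate
non-negatively with the cluster's mean feature; this makes signatures and
heatmaps reproducible across platforms. The per-cluster explained-variance
fraction is retained for audit.

### Known limitation of the CDF delta-area rule

For data whose true structure is a small number of *balanced, Gaussian*
clusters, the delta-area rule systematically overshoots. Splitting a
balanced cluster of s items moves on the order of (s/2)² pair-masses of
consensus weight, so the relative area change stays above 10% until the
clusters have been fragmented; for two balanced phenotypes of ~20 tumors
the rule selects 3–5 clusters even when the 2-cut of the consensus matrix
reproduces the planted labels exactly (adjusted Rand index 1.0 — see
`tests/test_phenotyping.py::TestAssignPhenotypes`). The rule behaves better
when extra clusters only peel outliers, which is typical of real cohorts but
not of Gaussian simulations. Planted 5-cluster feature structure sits right
at the rule's threshold ((s²/C(p,2))/A(4) ≈ 0.11 against the 0.10 cutoff),
so the recovery rate there is ~75–80% per seed rather than ~100%. We kept
the rule exactly as specified rather than re-tuning the cutoff.

## Tumor-level phenotyping

Tumors are clustered on their signature rows with Euclidean distance
(1 − r² across signature vectors is available via config; with few
signatures the correlation of short vectors is too noisy to recommend).
Signatures are deliberately **not** re-standardized: a PC score's variance
reflects how much coherent feature variance its cluster carries, and
equalizing it promotes noise signatures — in development, standardization
destroyed phenotype recovery while raw scores recovered planted labels
exactly. The phenotype count is chosen with the same consensus CDF rule
(k range 2–5 by default), and final labels come from a complete-linkage cut
of 1 − M at the selected k — standard consensus practice, and more stable
than a fresh cut of the raw distance. Label 1 is the larger phenotype (ties
broken by lowest tumor index).

SigClust asks whether the 2-way split is better than one Gaussian: the
statistic is the cluster index CI = within-cluster SS / total SS; the null
simulates from a zero-mean Gaussian with diagonal covariance equal to the
sample-covariance eigenvalues floored at a background variance estimated by
the median absolute deviation of all matrix entries (scaled to the normal);
each null draw is split by a deterministic 2-means (first-PC split then
Lloyd iterations), and p is the add-one-smoothed fraction of null CIs at or
below the observed CI. The same 2-means is exposed so calibration tests can
use an observed split drawn from the identical rule. The
covariance-shrinkage SigClust variants are out of scope.

## Survival models

The Cox partial likelihood is maximized by Newton–Raphson with step-halving;
convergence requires max|score| < 1e-8 or relative log-likelihood change
< 1e-10, with failure reported (never silently regularized) after 100
iterations; a singular information matrix (e.g. a constant covariate, or
condition number > 1e12 at the optimum) raises. Ties use Efron's
approximation by default; Breslow is available for cross-checks (both agree
to 1e-9 on tie-free data). Per-covariate p-values are Wald; model-level
comparisons use the likelihood-ratio test, including the comparison of the
multivariable model with vs without phenotype. Covariate coding: smoking
never-vs-former, line of therapy later-vs-first, sex M-vs-F, phenotype
2-vs-1 as 0/1 indicators; ECOG grade and mutation count continuous ("per
one increment").

Uno's concordance weights each usable ordered pair (event i before j,
t_i < τ) by Ĝ(t_i−)⁻², Ĝ the Kaplan–Meier estimate of censoring survival.
Ĝ is evaluated as a left limit, and ties between event and censoring times
are treated event-first, so a censoring at exactly t_i does not affect the
weight at t_i. τ defaults to the longest observed event time. Pairs with
Ĝ = 0 are excluded and counted in the result. Prediction ties score 0.5.
The c-statistic CI in reports is a percentile bootstrap (default 1000
resamples, seeded) that refits the Cox model per resample with τ held at its
full-sample value; the method is labeled in the report.

The univariable screen fits one Cox model per candidate and retains Wald
p ≤ 0.2, always keeping mutation count regardless of its p-value (it is the
ctDNA variable of primary interest). The median prognostic-score split uses
the full multivariable fit's linear predictor, sends ties to the low-score
group (deterministic and order-independent), and reports the two-group
log-rank test; medians that the Kaplan–Meier curve never reaches render as
"NR".

## Exact association tests

Fisher's exact test (2×2) and the Freeman–Halton r×c extension compute the
two-sided p as the sum of probabilities of margin-consistent tables no more
probable than the observed one, with a 1e-7 relative slack so floating-point
ties count as ties (the `fisher.test` convention). Factorials are log-gamma
in log space; r×c enumeration is exact for N ≤ 200 and for larger problems
a seeded margin-conditional Monte-Carlo (Patefield sampling) estimate is
available. In pipeline reports, crosstabs with (r−1)(c−1) > 8 switch to the
Monte-Carlo path (100 000 draws, fixed seed) to keep runs bounded; the
report labels the test accordingly. Mann–Whitney uses the exact null for
tie-free samples of ≤ 8 (normal approximation with tie and continuity
correction otherwise); Welch's t uses the Satterthwaite df. The published
Welch p = 0.8 for mutation counts cannot be checked from rounded summary
statistics alone; the raw-data test is what is implemented.

## Radiomic features

Discretization uses a fixed bin count (default 32) over the in-mask
intensity range — scale-free, which suits synthetic phantoms; fixed bin
width is not implemented. A constant region occupies the single level 1.
GLCM uses distance 1, symmetric accumulation, features averaged over the 13
unique 3D directions, as do GLRLM runs; GLSZM zones and GLDM dependences use
26-connectivity with GLDM α = 0; NGTDM statistics follow the standard
formulas with vanishing normalizers (constant regions) mapped to 0 and
logged, keeping constant phantoms usable. Surface area counts exposed voxel
faces — biased upward relative to marching cubes, acceptable because only
internal consistency is asserted. Elongation and flatness are √(λ2/λ1) and
√(λ3/λ1) of the physical-coordinate covariance. LoG filtering converts σ
(mm) to voxels per axis through the spacing and applies a spacing-aware
discrete Laplacian; the wavelet path is a one-level separable Haar transform
with the chosen subband upsampled back to grid shape. First-order skewness
and kurtosis are population moments (kurtosis non-excess). Exact numerical
parity with any particular feature library (and its 429-feature bank) is a
non-goal; the families, invariances (translation, normalization of every
texture matrix), and brute-force equivalences on tiny volumes are what the
tests pin down.

## The synthetic cohort

The generator emulates a 40-patient EGFR-mutant advanced-NSCLC cohort:
429 z-scorable features in 27 latent-factor clusters
(x = √ρ·factor + √(1−ρ)·noise, exact expected within-cluster correlation ρ,
default 0.8), two phenotypes at 52.5/47.5% prevalence separated by
`phenotype_shift` feature-sd units on half of the clusters (so not every
signature is informative, mimicking real signal sparsity; default shift 2),
covariate marginals matching the published cohort (age ≈ N(62, 8) clipped to
45–82; 72.5% female; 52.5% former smokers; ECOG on {0, 1, 2} with mean 0.55;
57.5% front-line therapy, optionally phenotype-dependent through a log-odds
parameter since the study's mechanism is unknown; mutation count
1 + Poisson(3) capped at 8, matching mean 4.0 and sd 1.76), exponential
event times with rate `baseline_rate`·exp(x'β) (default log-HRs: phenotype
ln 2.7, ECOG ln 2 — the effect sizes that carried signal in the motivating
cohort; death hazard scaled by 0.35 so deaths are rarer than progressions),
and independent exponential censoring truncated at 835 days. All draws come
from per-stage generators spawned from one config seed, so every output is
bit-reproducible.

What the generator does **not** emulate: CT physics, scanner and contrast
effects, heavy-tailed or skewed feature noise, informative censoring, or
outlier tumors. Consequences for interpretation: passing recovery tests
shows the pipeline is correct and well-calibrated under its own model
assumptions; it does not show the CDF selection rule finds the "right" k on
real cohorts (see the limitation above — real data's outlier structure is,
if anything, friendlier to the rule), nor that the planted effect sizes are
clinically realistic.

## Problem sizes and tolerances in tests

Oracle-equivalence tests run at exhaustive-enumeration scale (Cox n = 8
against a 1e-4 grid search, IPCW pairs at n = 10, complete linkage on 6
items, texture matrices on 4×4×4 volumes with 4 gray levels, PC1 against a
dense eigensolver). Recovery and calibration use 10 seeds for consensus-k
and phenotype recovery, 50 replicates at n = 500 for CI coverage, 1000
replicates at n = 60 for the nested-LRT type-I rate, 200 seeds with a
100-draw null for SigClust calibration, and n = 300 for the null
concordance — sizes chosen to keep Monte-Carlo error well inside the
asserted bands while the full suite stays fast on one CPU. End-to-end
determinism is asserted byte-for-byte on the serialized report.
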