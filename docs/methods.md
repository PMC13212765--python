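# Methods

This note documents the models, defaults and numerical choices behind
`radstrat`, and what the synthetic-data experiments do and do not show.

## Synthetic cohort model

`radstrat.synthdata.SyntheticConfig` defines the generative model. Per
patient *i*:

* a latent radiophenotype cluster `c_i ∈ {1..K}` (default K = 3, uniform);
  cluster means sit on scaled coordinate axes so that every pair of means is
  `cluster_separation` apart (default 3.0), in units of the patient-level
  standard deviation (`patient_sd`, default 1);
* a patient-level mean `μ_i = m_{c_i} + N(0, patient_sd² I)` in feature
  space (default 20 features);
* lesion count `n_i = 2 + Poisson(λ)`. λ defaults to 2.4: a shifted Poisson
  cannot produce both a median of 4 and a mean of 4.8 lesions per patient
  (a median of 4 caps the mean near 4.65); λ = 2.4 reproduces the median
  of 4 robustly at n = 361 (mean 4.4). Every patient has at least the two
  segmentable lesions the study design requires;
* lesion feature vectors `x_ij = μ_i + N(0, (lesion_sd · g_i)² I)`, where
  `g_i` is the dispersion multiplier of the patient's molecular group
  (defaults WT 1.0, sOA 1.0, nsOA 0.6 — non-smoker-alteration patients have
  radiologically more homogeneous lesions);
* the molecular group is drawn from a per-cluster probability vector, which
  is what links radiophenotype clusters to molecular labels;
* objective response is Bernoulli with
  `logit p = β₀ + β_D · dispersion_range_i + β_{c_i}`; overall survival is
  exponential with hazard `h₀ · exp(γ_D · dispersion_range_i)` under
  independent uniform censoring on [6, 72] months — exponential times and
  uniform censoring keep log-HR recovery checkable in closed form;
* a biopsied lesion exists for ~50% of patients and is the largest lesion
  with probability 0.611, otherwise uniform among the rest;
* volumes are 1 + lognormal(1, 0.8) cm³, above the 1 cm³ inclusion
  threshold;
* metastatic-site-style clinical covariates are sampled independently with
  fixed marginal frequencies; their joint distribution is a simplification,
  not an estimate.

All randomness descends from one root seed through named
`numpy.random.SeedSequence` children (one stream per concern: clusters,
lesion counts, features, labels, volumes, biopsy, outcomes, duplicates), so
identical configurations reproduce byte-identical tables and adding a new
stream cannot silently shift existing ones.

**Duplicate segmentations.** The duplicate table adds Gaussian noise to the
original features. In the two-way ANOVA behind ICC(2,1), disagreement
carried entirely by one rater contributes half its variance to the residual
mean square, so the one-sided noise variance is
`σ_e² = 2 σ_b² (1 − ICC)/ICC` (σ_b² = observed between-lesion variance) for
the empirical ICC of (original, duplicate) pairs to converge to the target;
with the unscaled formula the empirical ICC converges to ≈ √ICC-level values
(0.947 for a target of 0.9) instead.

What the generator does **not** emulate: correlated feature blocks (features
are conditionally independent given the patient), site- or organ-specific
lesion phenotypes, scanner/batch effects, informative censoring, and any
image-domain structure. Passing tests demonstrate that the pipeline recovers
known structure under its own assumptions — not that real CT cohorts satisfy
those assumptions.

## Feature filtering and normalization

* **ICC form:** two-way random effects, absolute agreement, single
  measurement — ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE))
  with k = 2 segmentations; the standard radiomics reproducibility choice.
  Cross-checked in the tests against an independent explicit
  sums-of-squares oracle and against `pingouin.intraclass_corr`. Features
  lacking duplicate measurements pass the ICC rule by default (the duplicate
  subsample is typically smaller than the cohort); fewer than 3 paired
  lesions yields a missing ICC with a warning.
* **Retention rule:** ICC strictly > 0.85 (configurable) AND not
  near-zero-variance. NZV uses the widely used caret-style defaults:
  flagged iff frequency ratio of the two most common values > 19 and
  distinct-value fraction < 10%; constant features always flagged.
* **Normalization order:** per feature, center-scale (mean/SD over the
  pooled lesion population, not per patient — pooling keeps Euclidean
  distances comparable across patients), then Yeo-Johnson with λ maximizing
  the Gaussian profile log-likelihood (bounded search on [−5, 5], tolerance
  1e-6, via `scipy.stats.yeojohnson_llf`). There is no re-standardization
  after the transform. All constants (mean, SD, λ) are stored in the
  `FeatureFilterReport` so held-out lesions are transformed by replay, never
  refit.

## Patient-level integration

Centroid = coordinate-wise mean of the patient's transformed lesion vectors.
Dispersion uses unweighted Euclidean distance in the transformed feature
space (all retained features weighted equally). The largest lesion is
defined by segmented volume, ties broken by lexicographically smallest
lesion id (logged). For a 2-lesion patient the two lesion-to-centroid
distances are mathematically identical, so the range is returned as an exact
0 rather than floating-point rounding noise. Patients without a biopsied
lesion are excluded from biopsied-lesion analyses rather than imputed.

## Consensus clustering

Defaults: 500 resamples (pipeline default 200 at desk scale), item fraction
0.8 without replacement, k ∈ [2, 8] (pipeline default [2, 6]). Inner
clusterer: Ward linkage on Euclidean distance, cut at k. Consensus(i,j) =
co-clustering count / co-sampling count (an error is raised if any pair is
never co-sampled). Final partition per k: average linkage on 1 − consensus.
One subsample sequence is shared across all k so co-sampling counts are
common.

**k selection.** k minimizes the PAC score (fraction of off-diagonal
consensus entries strictly inside (0.1, 0.9)), ties broken by larger
consensus-CDF delta-area and then smaller k. The delta-area-maximization
rule was evaluated and rejected: the delta-area of the smallest k is its raw
CDF area (there is nothing smaller to difference against), which dominates
the curve whenever k_min is even moderately stable — on three well-separated
equidistant synthetic blobs it selected k = 2 in roughly 70% of runs. Both
statistics are computed and reported. Fully degenerate diagnostics (every k
equally stable, e.g. identical rows) fall back to k_min with a warning.

**Merging.** Clusters below 5% of the cohort (configurable) are absorbed
into the cluster with the highest mean pairwise consensus to them, smallest
first, iteratively; a caller-supplied manual map (label → merged label) is
applied verbatim instead when given, and the applied map is always returned.

**ARI** is computed from the contingency-table form of the Hubert–Arabie
adjusted index; the tests verify it against exhaustive pair counting (n ≤
12) and `sklearn.metrics.adjusted_rand_score`. Between-representation ARIs
are computed on the intersection of assigned patients (biopsied-lesion
clustering covers only patients with an identified biopsied lesion).

## Association and survival statistics

* Wald 95% CIs use z = 1.959964 throughout.
* Contingency odds ratios: OR = ad/bc with CI
  `exp(ln OR ± z √(1/a+1/b+1/c+1/d))`; any zero cell yields a flagged
  degenerate estimate (0 or ∞ by direction) rather than an error or an
  automatic continuity correction (a Haldane–Anscombe correction is
  deliberately not applied by default).
* Test selection: categorical → chi-square, Fisher fallback for 2×2 tables
  with any expected cell < 5 (logged); numeric two-group → Shapiro–Wilk gate
  (both p > 0.05 → Student t, else Mann–Whitney); numeric multi-group →
  Kruskal–Wallis. The chosen test is always reported.
* Univariable screening fits one logistic model per candidate (statsmodels
  MLE); categorical candidates expand against a declared reference level.
  Quasi-separation (non-convergence or absurd standard errors) yields a
  flagged estimate, not a crash.
* Stepwise selection is backward elimination from the screened (p < 0.05)
  set: at each step the term with the largest removal p-value above 0.05 is
  dropped — Wald p for single-column terms, likelihood-ratio p for whole
  categorical blocks — with ties broken by name, making the procedure
  invariant to candidate ordering. Collinear columns are removed up front by
  a rank check, with a logged warning, and eliminations are traced step by
  step. Complete cases only.
* Survival: Kaplan–Meier and the log-rank test, and Cox
  proportional-hazards models with Efron tie handling, via lifelines.
  Constant covariates and monotone-likelihood failures are flagged.

## Monte Carlo cross-validation

Per split: stratified random 70/30 train/test partition; unpenalized
logistic regression fit on the training portion (scikit-learn with C = ∞ —
the same maximum-likelihood estimate as the statsmodels engine, refit
hundreds of times far faster); rank-based (Mann–Whitney, midrank ties)
AUROC on the held-out portion. All feature sets share one split sequence so
per-split differences are paired; the 95% CI is the empirical 2.5/97.5
percentile interval over splits. Splits missing a class are redrawn and
logged.

**Calibration checks.** On a single fixed dataset the MCCV mean converges to
that dataset's own chance association with the outcome (spread ≈ 0.03
across null datasets of n = 300), so calibration is assessed by averaging
over independent cohorts: 10 null cohorts × 100 splits for the
null check (mean AUROC ≈ 0.5), and 5 cohorts × 200 splits at n = 1000 for
the single shifted Gaussian feature, whose population AUC is
Φ(d/√2) ≈ 0.760 at d = 1.

## Problem sizes in the test suite

The simulation tests use deliberately modest sizes chosen to make their
statistical claims decisive while keeping the suite quick: consensus
recovery over 100 seeds of 60-patient blob cohorts at 100 resamples;
parameter recovery over 100 seeds at n = 1000 (Cox) and n = 500 (stepwise);
pipeline smoke tests at 60–150 patients. The acceptance script uses 30 seeds
for the per-seed simulations and the full 1000-split budget for MCCV.

## Known limitations

* The generator's independence assumptions (features, covariates) understate
  real-data correlation; filter and cluster behaviour on strongly correlated
  feature blocks is untested against ground truth.
* Consensus clustering with PAC selection can prefer larger k on
  structureless data; interpret chosen k together with the reported PAC and
  delta-area curves rather than in isolation.
* No penalized/Firth logistic fallback for separation: degenerate terms are
  flagged and excluded, matching a complete-case, unpenalized analysis.
* The pipeline's descriptive and survival outputs are only as meaningful as
  the synthetic outcome model when run without user data.
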