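# Methods

## Problem and approach

IgA nephropathy (IgAN) progresses very heterogeneously: some patients remain
stable for decades on supportive care while others reach kidney failure
within a few years. `nephronet` implements a risk-stratification pipeline
that characterises each patient not by raw indicator values but by how the
patient *perturbs* the correlation structure of a healthy reference cohort,
then clusters patients on graph summaries of those perturbation networks.

The stages are:

1. **Preprocessing.** Missing clinical indicators are imputed by iterative
   chained linear regression; features are standardised to zero mean / unit
   variance; a manifold embedding (UMAP) reduces the feature space to 2-D.
   Every transform is fitted on the training ("cluster") cohort and frozen;
   external patients pass through the stored state and are never used to
   refit anything.
2. **Sample-specific networks (SSN).** For indicators $i,j$ with reference
   Pearson correlation $r_{ij}$ over $n$ healthy samples, adding one patient
   and recomputing gives the perturbation
   $\Delta r_{ij} = r_{ij}^{(n+1)} - r_{ij}$, with null-hypothesis z-score

   $$Z_{ij} = \frac{\Delta r_{ij}}{(1 - r_{ij}^2)/(n-1)}$$

   referred to a standard normal, two-sided. Pairs with $p < \alpha$
   (strictly; default $\alpha = 0.05$) become edges of the patient's
   undirected perturbation network. $|r_{ij}|$ is clipped to
   $1 - 10^{-12}$ so the variance term never vanishes. The perturbed
   correlation is obtained by a rank-one update of the reference mean and
   centered cross-product matrix ($O(F^2)$ per patient); a brute-force
   recomputation with `np.corrcoef` is kept as an independent test oracle.
3. **Graph features.** Each network is summarised by 46 named attributes on
   the default 40-indicator schema: the degree of every indicator node
   (40, node level), diameter of the largest connected component and
   average clustering coefficient (2, subgraph level), and non-isolated
   node count, edge count, connected-component count over non-isolated
   nodes, and edge density (4, global level). For an $F$-indicator schema
   the catalog length is $F + 6$.
4. **Stratification.** Six schemes — {k-means, Ward agglomerative} ×
   {demographic+renal indicators, all indicators, network features} — each
   cut at $k = 4$. KMN (k-means on network features) is the recommended
   scheme. Clusters are renumbered by severity: stratum 1 has the highest
   mean eGFR, stratum 4 the lowest, ties broken by rising mean 24 h urine
   protein. External patients are processed sequentially through the
   frozen pipeline and assigned to the nearest training centroid
   (hierarchical schemes use training-cluster means as centroids);
   equidistant ties go to the lowest stratum index.
5. **Evaluation.** Kaplan–Meier curves, K-group log-rank, multivariable Cox
   PH (Efron ties) adjusted for age, sex, urine protein, urinary red cells,
   renal function and blood pressure, with stratum indicator variables
   against stratum 1. The *cluster-label AUC* trains a gradient-boosted
   classifier whose only input is the stratum label; because a single
   categorical predictor's ROC is fully determined by per-stratum event
   rates, the analytic rank-AUC of those rates is computed as an oracle the
   model must match. Cross-validated AUC is the mean of per-fold held-out
   AUCs (pooling scores across folds would mix fold-specific rate
   estimates and bias the estimate down). Scheme comparison resamples 80%
   of patients without replacement for 10 rounds and applies pairwise
   two-sided Mann–Whitney U to the AUC lists. Effect sizes use Cohen d
   with the pooled-variance denominator.
6. **Interpretation.** The unsupervised strata become surrogate labels for
   a multiclass gradient-boosted classifier over the 46 attributes
   (pre-reduction, so attributions speak the language of network
   parameters), assessed by stratified 10-fold CV; per-feature Shapley
   values come from the booster's exact TreeSHAP path and satisfy local
   accuracy (attributions + base value reconstruct the margin). A
   permutation-importance fallback is flagged in the report if Shapley
   attribution is unavailable for a model.
7. **Omics contrasts.** Fixed order: QC filter (drop features with
   CV > 20% over QC replicate injections) → sum normalization (close each
   sample to 1) → PLS-DA (NIPALS; ±1 response for two classes, one-hot for
   four, SSY pooled over response columns) → VIP,

   $$\mathrm{VIP}_j = \sqrt{p \, \frac{\sum_a \mathrm{SSY}_a \, (w_{aj}/\lVert w_a \rVert)^2}{\sum_a \mathrm{SSY}_a}},$$

   which forces $\overline{\mathrm{VIP}^2} = 1$; VIP > 1 flags a feature as
   discriminating. Strata 1–2 regroup to "low risk", 3–4 to "high risk".
   Correlation networks add an edge for any pair with $p < 0.05$ (no
   multiplicity correction by default, mirroring common practice; a
   Bonferroni flag exists). Mantel tests (default Spearman, 999
   permutations) relate clinical-indicator distances to omics distances.

## Synthetic cohorts

No patient-level data are distributed, so the package ships a generator
whose defaults are its reference study conditions; all tests and the
acceptance script run on its output.

* **Reference cohort** — 50 healthy samples from a multivariate normal with
  a block-diagonal correlation matrix over six physiological blocks
  (demographic/lifestyle, renal chemistry + blood pressure, biopsy
  pathology, liver panel, lipid/metabolic, haematology/comorbidity), each
  block from a rank-2 factor model. Cross-block reference correlation is
  zero, which is what lets subtype-specific block edits stay positive
  semi-definite without touching anything else.
* **Patients** — four latent subtypes (equal mixing by default), each a
  shifted-mean, perturbed-correlation multivariate normal. The mean
  structure is a monotone renal backbone (eGFR −1.0, 24 h urine protein
  +0.9, creatinine +0.6 … reference-sd units per subtype step, scaled by
  `mean_shift_scale`, default 1.5) plus a per-subtype clinical phenotype
  signature: near-healthy; hematuric (urinary red cells, mesangial
  hypercellularity, IgA deposit intensity, liver enzymes); proteinuric /
  nephrotic-range (hypoalbuminaemia, dyslipidaemia, segmental sclerosis);
  progressive function decline (creatinine, hypertension, anaemia, tubular
  atrophy). The phenotype signatures are what make the subtypes *clusters*
  rather than quantile slices of one severity continuum: a pure gradient
  leaves adjacent subtypes overlapping beyond what any unsupervised method
  can separate, while distinct presentations with a shared severity
  backbone keep mean eGFR strictly decreasing and urine protein strictly
  increasing across subtypes 1→4. Binary/ordinal indicators (smoking,
  diabetes, MEST-C scores, deposit intensities) are thresholded from the
  same latent Gaussian at quantiles chosen to hit realistic prevalences,
  so one correlation machinery serves all indicator kinds. Missingness is
  completely at random at rate 0.05.
* **Correlation perturbation** — for subtypes 2–4 the renal-chemistry block
  is blended, $(1-\gamma) C + \gamma\, \tilde C_s$ with $\gamma = 0.5$ by
  default, where $\tilde C_s$ is the block conjugated by a random
  orthogonal rotation and renormalised to unit diagonal (a valid
  correlation matrix, so the convex blend is too; a nearest-PSD projection
  exists as a numerical backstop). Entries outside the block equal the
  reference exactly.
* **Survival** — event times are exponential with hazard = baseline
  (0.002/month) × subtype multiplier (1, 2, 4, 8) × treatment-arm
  multiplier, censored uniformly on (0, 120) months. Treatment arms
  {SC, GS, II, GS+II} are drawn per subtype with probabilities rising
  toward immunosuppression in the high-risk subtypes; the combined GS+II
  arm multiplies the hazard by 0.3 in subtypes 3–4 only (protective), and
  all other arm effects are neutral. Exponential (not Weibull) times keep
  closed-form means for testing.
* **Omics** — log-normal metabolite intensities (200 features) with ±1 sd
  log-scale shifts on a random 15% of features between high-risk (subtypes
  3–4) and low-risk samples; QC replicate injections with per-feature CVs
  drawn uniformly on [0.05, 0.40], deliberately straddling the 20%
  threshold. Genus-level abundances (60 genera) are logistic-normal and
  row-closed to 1 with analogous group shifts.
* **Trajectories** — serum creatinine and urine protein at visits
  {0, 6, 12, 24, 36} months with subtype-dependent drift (stable in
  subtype 1, treatment dip then rebound in 3, steady creatinine rise in 4).

What the generator does *not* emulate: informative censoring, longitudinal
indicator dynamics beyond the five visits, measurement batch effects,
realistic pharmacology, and any real cohort's effect sizes or subtype
proportions. Tests passing on this generator demonstrate that the pipeline
recovers structure *of the kind it assumes*; they say nothing about how
sharply real IgAN cohorts cluster.

## Numerical and design choices

* **"Multilinear" imputation** is realised as scikit-learn's
  `IterativeImputer` with plain linear regression, mean initialisation,
  round-robin sweeps (max 10) and tolerance 1e-3: deterministic and
  row-permutation-equivariant. Continuous imputations are clipped to the
  column's observed range; binary/ordinal imputations snap to the nearest
  valid coded level; observed cells are never altered.
* **Reduction defaults**: UMAP, 2 components, neighbourhood 100, min_dist
  0.1, fixed seeds for both fit and transform. The neighbourhood was set by
  comparing the unsupervised stage against a supervised probe on the same
  features across several generator seeds: with the default cohort size
  (~1000), small neighbourhoods leave the manifold stage the accuracy
  bottleneck, while ~100 neighbours recover the global four-cluster
  geometry stably. A deterministic PCA reduction is available
  (`method="pca"`) for exact-reproducibility tests and small cohorts.
* **k-means** runs 50 restarts keeping the lowest inertia; hierarchical
  clustering is Ward linkage. $k = 4$ everywhere, configurable.
* **Degenerate graph conventions**: empty graph → diameter 0, density 0,
  component count 0; nodes with degree < 2 contribute 0 to the average
  clustering coefficient (averaged over all nodes). These keep all 46
  features finite.
* **Constant features** (e.g. the component count when every patient's
  network is dense) are dropped with a warning before standardisation
  inside scheme fitting; the standalone standardiser treats a
  zero-variance column as an error.
* **Edge rule**: strict $p < \alpha$; thresholding on p (not |Z| or top-k)
  is a documented choice, exposed as the `alpha` parameter.
* **Problem sizes**: default end-to-end runs use 600 patients; recovery
  checks use 1000 patients per seed; power-style checks use 50 replicates
  of 400 patients. These sizes give stable statistics while keeping a full
  test run in minutes.

## Known limitations

* The 46-attribute catalog is one reconstruction of a node/subgraph/global
  feature hierarchy; other degree-compatible summaries would also yield 46
  names. The catalog is data, not code — alternative catalogs plug in.
* Assignment of external patients under hierarchical schemes (nearest
  training-cluster mean in embedded space) is an extension; only the
  k-means path has a canonical out-of-sample rule.
* UMAP coordinates are reproducible for a fixed seed on one platform but
  not across BLAS/numba builds; cross-platform exactness requires the PCA
  fallback.
* The cluster-label AUC concerns the *full-follow-up* composite event
  indicator; no fixed-horizon or time-dependent AUC is implemented.
* PLS-DA significance is not permutation-tested by default; the
  `explained_y_fraction` field supports a user-side permutation test.
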