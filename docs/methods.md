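# Methods

This note documents the statistical procedures implemented in `pancanmet`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## 1. Conditional likelihood and its reduction

All risk models condition on the 1:1 matched design. For a pair with case
covariates x₁ and control covariates x₀, the conditional probability that
member 1 is the case is exp(β′x₁)/(exp(β′x₁)+exp(β′x₀)) = σ(β′d) with
d = x₁ − x₀. The package therefore works throughout on pair-difference
rows with an intercept-free logistic likelihood and all responses equal to
one. This reduction is exact (it is unit-tested against brute-force
enumeration at 1e-12) and makes any L1 solver applicable. Matching factors
(study, batch, sex, age) are constant within a pair and drop out of d.

## 2. Data-shared lasso

Each type-k coefficient vector is parameterised β_k = μ + δ_k and the
stacked design Z (overall block + K deviation blocks) is penalised with

  (1/n) Σᵢ log(1+exp(−zᵢ′β)) + λ Σⱼ wⱼ|βⱼ|.

**Penalty factors.** Overall block w = 1; deviation block k gets
r_k = √(n_k/n̄) by default ("sqrt_nk"), with r_k = 1 ("unit") available.
The sample-size weighting follows the data-shared-lasso literature's
convention: a deviation claimed for a large type must be supported by
proportionally more evidence, and small types (here, a gallbladder-cancer
stratum an order of magnitude smaller than the breast stratum) are not
the cheapest place for the optimiser to park spurious deviations.

**Solver.** Iteratively reweighted least squares with cyclic coordinate
descent on the working quadratic (soft-thresholding updates), warm starts
along a geometric λ path, and an explicit KKT check of the exact objective
as the convergence criterion (default residual ≤ 1e-8; the returned
diagnostics carry the achieved residual). Infinite penalty factors pin
coefficients at exactly zero, which gives the plain-lasso limit used in
tests. Inner loops are numba-jitted; without numba the same code runs as
plain Python. IRLS weights are floored at 1e-6 and coefficient magnitudes
above 100 abort with a separation diagnostic.

**λ selection.** Pair-level K-fold cross-validation (default 10 folds),
stratified by cancer type so every fold preserves the type composition;
the criterion is held-out conditional deviance per pair. Both the
CV-minimum and the 1-SE rule are implemented; **the 1-SE rule is the
default**. On synthetic cohorts the minimum rule admitted dozens of noise
terms (overall-term false-discovery proportions near 0.7, and bootstrap
selection of genuinely null terms above 50% on unlucky cohorts), whereas
the 1-SE rule yields supports of a handful of terms among hundreds of
candidates — the sparsity regime the method is designed for — at no
measurable cost in sensitivity for effects ≥ 0.15 per SD at the sample
sizes studied here.

**Scaling.** Features are standardized to unit variance on control
samples before differencing, so all log-ORs are per control-SD
(epidemiological convention); BMI residualization (per-feature simple
linear regression over all analysis samples) precedes standardization.
Support is defined by |β| > 1e-8 after convergence.

## 3. Variable clustering

Metabolite panels contain blocks of near-collinear assays. On control
samples only (using cases would let case status drive the correlation
substrate), variables are clustered agglomeratively under the
homogeneity criterion H(cluster) = λ₁(R), the leading eigenvalue of the
cluster's correlation matrix — equivalently max over synthetic scores y of
Σⱼ corr²(xⱼ, y). Each merge joins the pair of clusters minimising the loss
of total homogeneity; since λ₁(union) ≤ λ₁(A) + λ₁(B), every loss is
non-negative and the criterion is monotone along the tree. Ties are broken
lexicographically by member label, so the tree is platform-deterministic.

The retained partition is the smallest cluster count, scanning tree cuts
from one cluster upward, in which every representative explains at least
80% of its cluster's variance (λ₁/p ≥ 0.80). Cuts of the already-built
tree are used rather than re-optimised partitions — the scan is then
monotone and cheap, and on block-structured data the two coincide.
Representatives are unit-norm first principal components of the
standardized members, sign-oriented so the mean loading is positive;
cluster features are named `<first member>_clus`. Cases are scored with
control-derived means/SDs and loadings. The cluster model is fit once and
held fixed across bootstrap replicates (re-clustering per replicate is
available behind a flag but not the default, since the downstream
selection — not the clustering — is the inferential target).

## 4. Pre-processing

Fixed order: metabolite filter → sample filter → outlier removal → limit
imputation → batch-median imputation → log transform.

- *Missingness filters.* A metabolite is dropped iff its fraction of
  status-`missing` cells strictly exceeds 25% in at least one study; then
  samples with strictly more than 25% missing cells over retained
  metabolites are dropped together with their pair partners (the matched
  design is preserved at every exclusion). Censored cells (below-LOD/LLOQ,
  above-ULOQ) count as observed for the filters: they are imputed by rule,
  not treated as missing.
- *Outliers.* Within each study: log concentrations, robust per-metabolite
  centring/scaling (median, MAD·1.4826, SD fallback), PCA on the
  correlation scale, retention of components covering 95% of variance,
  and flagging of Mahalanobis distances beyond the χ² 0.999 quantile at
  the retained dimensionality. The statistic is computed on the log scale
  even though the pipeline's log stage comes later: the χ² reference
  presumes roughly symmetric marginals, and raw concentrations are
  log-normal (on clean synthetic data the raw-scale rule flagged ~10% of
  samples; the log-scale rule flags none). Both cutoffs are
  config-exposed. Studies with fewer samples than retained components are
  skipped with a warning.
- *Censoring imputation.* below-LOD → LOD/2, below-LLOQ → LLOQ/2,
  above-ULOQ → ULOQ, per batch; a cell whose batch limit is unknown uses
  the study-specific median of known batch limits for that metabolite, and
  a censored cell with no limit recoverable anywhere in its study is an
  error naming the metabolite and batch.
- *Remaining missing cells* take the batch median of non-missing values
  (study median, with a warning, for an all-missing batch).
- *Log transform* is natural log (config-exposed base).

## 5. Post-selection inference and secondary analyses

The unpenalized refit ("lasso-OLS hybrid") maximises the conditional
likelihood over exactly the selected columns by Newton-Raphson with step
halving; Wald 95% CIs are reported and flagged as post-selection. No
selective-inference correction is applied — on synthetic cohorts at half
study scale the empirical coverage of these CIs for true selected terms is
≈ 97% (mild winner's-curse undercoverage appears only for borderline
terms). Separation or aliasing marks individual terms non-estimable rather
than failing the fit.

- *Extended type-specific comparison.* For each feature with a selected
  overall term, the restricted (selected) model is compared by LRT to the
  model replacing that feature's overall + selected deviations with K
  fully type-specific terms; df = K − (1 + #selected deviations).
- *Linearity.* Natural cubic splines with 4 regression df: interior knots
  at the 0.25/0.5/0.75 quantiles and boundary knots at 0.05/0.95, in a
  truncated-power natural-spline basis whose leading column is exactly x —
  so after pair-differencing the linear model is nested and the LRT has
  3 df. Basis built on pooled sample values, then differenced.
- *BMI effect modification.* Matching broken; the feature is batch-median
  centred (simple location correction), and a logistic model of case
  status on feature, BMI, feature×BMI, study indicators and the matching
  factors sex/age is compared by 1-df LRT to the no-interaction model.
  The p-value is invariant to BMI centring. Empirical size at nominal 5%
  is 4–7% over 400–600 null replicates.
- *Sensitivity refits.* Named pair filters (≥2y / ≥7y follow-up,
  hormone-user reintegration, none) plus extra covariates entered as
  case-control differences (one-hot differences for categoricals), with
  the support held fixed; filters that empty a type drop that type's
  deviation terms with a warning. All variants emit the same table schema.
- *Univariate track.* Per (feature, type) single-feature conditional
  logistic fits plus a pooled all-types fit, BMI-adjusted by
  residualization (default, consistent with the multivariate track) or by
  a BMI-difference covariate; Benjamini-Hochberg q-values within each
  cancer type.

## 6. Bootstrap stability

B replicates (default 100) resample matched pairs with replacement,
stratified by cancer type (each replicate keeps the per-type sample
sizes; unstratified resampling is available). Within every replicate the
analysis is re-run from BMI residualization onward — fresh
standardization on the replicate's controls, fresh CV folds, fresh λ —
and the support and coefficients are recorded. Reports give per-term
selection proportions and the average penalized log-OR over selecting
replicates. Reporting thresholds are strict: main-run terms with
proportion > 0.50 count as replicated; non-main-run terms with
proportion > 0.55 are listed as additional candidates. A master seed
spawns one child RNG stream per replicate, and draws are made from
id-sorted pairs, so reports are bit-reproducible and invariant to input
row order; failed replicates are excluded from the denominator and
logged.

## 7. Synthetic cohorts

The generator emulates the structure the analysis assumes: 8 cancer types
recruited through 7 studies (colorectal pairs split across two studies;
hepatocellular and gallbladder/biliary types share the liver study; both
prostate types share one study) with exact per-type pair counts
(1088/1500/689/511/85/121/533/1301 at full scale), 117 metabolites of
which 100 lie in 33 block-exchangeable clusters of sizes 2–6 at
intra-correlation 0.85, batch-specific limit censoring (5% of the control
distribution below the limit by default; limits dropped from the metadata
at a small rate to exercise the study-median fallback), 1% missing cells,
additive N(0, 0.1) batch shifts on the log scale, log-normal BMI acting on
both metabolite levels and risk, and sparse effects (six inverse and three
positive overall log-ORs of 0.15–0.25 per latent SD, three type-specific
deviations of ±0.3). Case status is drawn by the within-pair conditional
mechanism — the case is member i with probability
exp(η_i)/(exp(η₁)+exp(η₂)) — so the fitted conditional model is the true
model and parameter recovery is well-posed.

Not emulated: real Biocrates signal distributions beyond log-normality,
plate drift, assay-specific measurement error, correlation between BMI and
the matching factors, and any biological pathway structure. Passing tests
therefore certify the statistical machinery (selection, estimation,
calibration, stability) under the declared generative structure, not
performance on real mass-spectrometry data.

## 8. Problem sizes and numerical choices

Test and acceptance runs use desk-scale versions of the study conditions,
chosen as the package's own validation sizes: parameter recovery uses the
8-type design at half the full pair counts (floored at 75 pairs/type,
≈ 2,960 pairs) with 50 features over 20 seeds and 5-fold CV on a 25-point
λ path (ratio 0.05); calibration uses 400–600 null replicates of 400
pairs; stability uses B = 25 with 4 types × 500 pairs. Key tolerances:
likelihood-reduction exactness 1e-12, solver-vs-oracle objective gap
1e-8, KKT residual 1e-6, support zero-tolerance 1e-8. Degenerate inputs
(constant BMI, zero-variance features, empty types, separation,
unrecoverable limits) raise informative errors or flag terms
non-estimable, as documented per function.
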