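# Methods

This note documents the statistical procedures implemented in `omniblock`,
the defaults and their rationale, what the synthetic generator does and does
not emulate, and the package's known limitations.

## Data model

A `FeatureTable` is a samples × features matrix of non-negative intensities
(arbitrary units; `NaN` = missing, zeros are measured values) with
per-sample metadata (role `study`/`qc`/`blank`, unique injection order,
group label for study samples, optional matched-pair id and subgroup
columns) and per-feature metadata (assay `metabolomics`/`lipidomics`,
annotation, optional functional block and lipid class). On disk it is three
plain CSVs so that sample roles and injection orders stay first-class —
the QC logic depends on metadata integrity. All randomized operations take
an explicit seed, and a run writes its resolved configuration next to its
outputs.

## Preprocessing chain

Applied per assay (metabolomics and lipidomics come from separate
analytical runs with their own QC/blank series), then joined on sample id:

1. **Blank removal.** Keep a feature iff mean QC intensity ≥ 3 × mean blank
   intensity (boundary inclusive). The 3:1 signal-to-blank rule is the
   common untargeted-QA convention; the ratio is configurable.
2. **Drift correction.** Per feature, a local-linear LOESS curve (tricube
   weights, default span 0.75) of QC intensity vs injection order, evaluated
   at every injection by interpolation and constant extrapolation beyond the
   terminal QCs; intensities are divided by the fitted relative drift.
   A final renormalization preserves each feature's QC median exactly.
   Features with a non-positive fitted curve are left uncorrected and
   flagged. Requires ≥ 4 QCs.
3. **CV filter.** Keep features with QC CV = sd/mean strictly below 0.30
   (the strict inequality mirrors the usual "< 30%" phrasing). Features with
   fewer than two QC observations are removed and counted separately.
4. **PQN.** Reference = per-feature median over study samples; each
   study/QC sample is divided by the median quotient of its spectrum to the
   reference (features positive in both). The reference is recomputed and
   the step iterated to a fixed point (tolerance 1e-12, ≤ 500 iterations),
   which makes the operation idempotent — a property the single-pass
   textbook PQN only satisfies approximately (~1e-5 residual quotients).
   The per-sample product of quotients is reported as the dilution factor.
5. **Scaling.** Column mean-centering with unit-variance (default), Pareto
   or no scaling, fitted on study rows; zero-variance columns are dropped
   with a warning; residual missing values are imputed at the column mean
   (zero after centering). Centering/scaling vectors are retained to project
   new samples.
6. **Outlier flags.** PCA on the scaled study rows; Hotelling T² over the
   first components against the F-distribution limit at the 0.99 quantile.
   Flags are advisory — exclusion is an explicit user action.

Step order follows the conventional acquisition-to-analysis narrative;
feature counts are non-increasing within each assay's chain. The LOESS step
necessarily absorbs a small part of the analytical noise, so post-correction
QC CVs sit a few percent (relative) below their generative targets; the
test suite accounts for this.

## Latent-variable models

All fits expect a centered (usually unit-variance) matrix.

* **PCA** is NIPALS with missing-value skipping in both regression steps,
  components ordered by explained variance, sign fixed by making the
  largest-|loading| entry positive. On complete data it agrees with the
  dense eigendecomposition to 1e-8 (tested).
* **PLS-DA** is single-response NIPALS (PLS1) on a centered 0/1 group
  indicator — the strictly two-group setting; multi-class is out of scope.
  At full rank the fitted response equals the least-squares fit (tested).
  R2Y = 1 − SS_res/SS_tot; per-component explained response SS
  `SS_a = c_a² t_aᵀt_a` feeds the VIP.
* **OPLS-DA** extracts `n_orthogonal` response-orthogonal components
  (weight = loading minus its projection on the predictive weight, the
  standard orthogonal-projection scheme), deflates, then fits one predictive
  component. With zero orthogonal components it equals PLS-DA with one
  component exactly; predictive and orthogonal scores are mutually
  orthogonal by construction.
* **VIP** uses the predictive components only; mean(VIP²) = 1 identically.
* **Cross-validation** uses stratified random folds (default 7), refolding
  with a new seed if a fold loses a class (≤ 10 attempts). Each training
  fold is centered/scaled independently; Q² = 1 − PRESS/SS_tot from held-out
  predictions. The commercial every-nth deterministic fold scheme is not
  replicated; the fold seed makes runs reproducible.
* **Permutation test** (default 200 permutations) recomputes Q² under label
  permutation; p = (1 + #{Q²_perm ≥ Q²_obs})/(n_perm + 1), so the smallest
  attainable p is 1/201. Under the null this p is uniform (calibrated in the
  test suite).
* **CV-ANOVA** is implemented as the PRESS-based approximation
  F = ((SS_tot − PRESS)/A)/(PRESS/(n − A − 1)), since the cited procedure's
  exact residual bookkeeping is not public. It is reported alongside, never
  instead of, the permutation test.
* The number of components defaults to the largest A ≤ 5 with positive
  incremental Q².

## Multiblock analysis

Metabolites are grouped by curated functional block (from the feature
metadata or a two-column TSV); lipids by Ward hierarchical clustering
(Euclidean, features as points over the scaled study samples) cut at k = 11
clusters by default. Each block is compressed to its OPLS-DA predictive
score (1 orthogonal component by default; 0 for blocks of < 3 features;
single-feature blocks pass through the scaled feature), standardized to
unit variance and sign-aligned to positive correlation with the response.

Block scores are weighted by `sqrt(n_k)` normalized so Σω² equals the
number of blocks — a block's influence grows with the number of metabolites
it summarizes; the opposite (dominance-suppressing) `1/sqrt(n_k)` and no
weighting are available, as the literature uses both conventions. The
hierarchical PLS-DA is then an ordinary PLS-DA on the weighted score
matrix, with block-level VIP, Q², permutation p and CV-ANOVA.

Block selection requires VIP > 1 **and** Benjamini–Yekutieli q < 0.05 of a
Welch t-test on the composite score. Composite scores are supervised, so
this t-test inherits their optimism (it is reported as published practice);
the permutation test of the hierarchical model is the honest global check.
A practical consequence, visible on synthetic data: a large *null* block's
composite score acquires an optimism correlation of roughly sqrt(p_eff/n)
with the response, so weakly affected small blocks cannot be strictly
separated from large null blocks by VIP alone.

## Feature selection and signatures

Signed fold change = case/control mean ratio r reported as r when r ≥ 1,
else −1/r (a −1.12 means a 12% decrease); antisymmetric under group
exchange. Univariate tests default to Welch's t on log intensities (the log
makes the fold-change convention symmetric); Student's t, the matched-pair
t (complete pairs required) and Mann–Whitney are available.
Benjamini–Yekutieli adjustment (valid under arbitrary dependence) gives
q-values; feature selection uses VIP > 1 and, by default, the **raw** p
< 0.05 — matching the common practice of reporting raw p for top features —
with an explicit `use_adjusted` switch. Signature comparison enumerates all
Venn regions of 2–4 selected-feature sets; beyond 4 a membership table
should be used. Subgroup signatures are re-runs of the pipeline on filtered
sample sets, not bespoke code paths.

## Partial-correlation network

The correlation matrix R of the (unweighted) block scores is shrunk to
(1 − λ)R + λI with the analytic variance-minimizing intensity
λ* = Σ var(r_ij)/Σ r_ij² (clamped to [0, 1]) — the Schäfer–Strimmer
estimator, needed because the number of blocks is comparable to the sample
count. Partial correlations are −Ω_ij/√(Ω_ii Ω_jj) from the inverse Ω. Edge
p-values use the t statistic r√(df/(1−r²)) with df = n − G when positive,
else a Fisher-z normal approximation with n − 3 effective observations;
because the shrunk estimates are deflated, these p-values are conservative.
The empirical-null mixture modeling of the R package commonly used for this
step is deliberately replaced by this simpler, testable approximation.
Edges are kept at the permissive p ≤ 0.25 by default (the "initial network"
convention); betweenness centrality is computed on the unweighted
thresholded graph (no edge-weighting rule is standard here) and exported
with the graph as GraphML, SIF text and CSVs.

## Enrichment

Over-representation only (the selected set is discrete, so a ranked GSEA
variant would not match the workflow): p = P(X ≥ k) for
X ~ Hypergeom(N, K, n) via the survival function, with
Benjamini–Hochberg q across pathways (the B-Y choice applies to the omics
feature tests, where dependence is arbitrary; pathway tests are adjusted
with the conventional B-H). The background universe is the annotated
metabolites that survived preprocessing, not the whole catalog — using the
full catalog would inflate significance with unmeasured compounds. Name
matching is case-insensitive and whitespace-normalized, never fuzzy. The
hypergeometric p is discrete, so its null distribution is super-uniform
(P(p ≤ α) ≤ α) rather than exactly uniform.

## Synthetic cohort generator

Per feature j: baseline log-intensity μ_j ~ N(log 1e5, 1); target QC CV
drawn uniformly from [0.10, 0.40] (straddling the 0.30 filter cutoff) and
converted to the log-normal noise sd σ_j = sqrt(log(1 + CV²)); a block-
shared standard-normal factor with loading σ_j·sqrt(ρ/(1−ρ)) so that the
pairwise within-block correlation is ρ = 0.5; a signed group effect
log|FC| (magnitudes uniform on [1.05, 1.9], random sign, planted on half
the blocks of each assay — close to the fractions such studies report) added
to case samples; everything exponentiated and multiplied by a smooth
per-feature drift 1 + 0.2·cos(2π(f u + φ)) in the normalized injection
position (f ~ U(0.5, 1.5), φ ~ U(0, 1)). QC samples are draws at the pooled
mean (halfway between group means on the log scale, no block factor, same
noise), matching their role as pooled aliquots; blanks sit at 1/20 of the
median baseline; a QC occupies every 5th injection after a leading run of
blanks; missingness is completely at random (0 by default). Matched pairs
share a `pair_id` but induce no extra correlation (matching is on
covariates, not repeated measures).

**What it does not emulate:** adducts/isotopes, retention-time drift,
batch-to-batch effects (single analytical series by design), censoring-type
missingness at the detection limit, heavy-tailed noise, or biologically
structured cross-block correlation. Passing recovery tests therefore shows
the chain is correct under log-normal block-factor data, not that it is
robust to everything real cohorts do.

**Study-condition defaults:** 97 samples per group, 228 metabolite features
in 54 functional blocks, 335 lipid features in 11 clusters, QC interval 5,
drift amplitude 0.2, within-block ρ 0.5. Where the emulated design
prescribes no value (ρ, CV range, affected fraction), defaults were chosen
once as plausible for plasma LC-MS cohorts and are tunable.

## Numerical choices

NIPALS tolerance 1e-12 with ≤ 1000 iterations (error names the component on
non-convergence); deterministic sign conventions everywhere (largest
|loading| positive; block scores aligned to positive response correlation);
Ward ties broken deterministically by feature order; LOESS evaluated with
constant extrapolation beyond terminal QCs; fold seeds derived from the run
seed; all CSVs written with fixed float formatting so identical seeds give
byte-identical outputs.

## Known limitations

* The block t-test on supervised composite scores is anti-conservative by
  construction (reported because it is field practice); rely on the
  permutation p for the global claim.
* Hierarchical VIP cannot strictly separate weakly affected small blocks
  from large null blocks (see Multiblock above); rankings should be read
  together with the per-block q-values, and block-level claims validated by
  permutation.
* CV-ANOVA is an approximation; its p-values are not exchangeable with the
  commercial implementation's.
* Two groups only; covariate-adjusted models are out of scope (confounding
  is assumed handled by design matching).
* Preprocessing assumes one analytical series per assay; multi-batch
  correction is not implemented.
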