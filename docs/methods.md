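# Methods

## Overview

`tmesf` implements an analysis pipeline for multi-sample single-cell RNA-seq
cohorts of solid tumors, centred on the question of how the abundance of
mature regulatory dendritic cells (mregDC, as a fraction of conventional
dendritic cells) relates to the rest of the tumor microenvironment: which
subtype compositions co-vary with it, whether it stratifies patient
survival, and — the core method — which binary cell states and genes track
the mregDC-high vs -low split once covariates and sample-level
heterogeneity are adjusted for.

All stages are exercised against a synthetic cohort generator with known
ground truth, so every statistical guarantee stated below is backed by a
test that measures it.

## The NB mixed model

Counts for gene *g* in cell *i* of sample *s(i)* are modelled as negative
binomial with

```
log mu_gi = log N_i + x_i' beta_g + gamma_g z_i + u_{g,s(i)},
u_{g,s} ~ Normal(0, sigma2_g),   Var(y|mu) = mu + mu^2 / phi_g
```

* `N_i` — total molecules detected in the cell; the offset enters as
  `log N_i` (the standard NB-GLM convention for a count offset).
* `x_i` — intercept, standardized age, dummy-coded sex / tissue /
  treatment state / treatment group (first level alphabetically dropped),
  and the cell-level fractions of mitochondrial and ribosomal reads.
  Columns constant within the analysed subset are dropped and recorded.
  Additionally, sample-level columns are capped at `n_samples - 2` and
  collinear columns are removed greedily (both recorded): with few samples
  a saturated sample-level design would absorb all between-sample variation
  and make `sigma2` unidentifiable.
* `z_i` — the binary latent state (absent in stage-0 fits).
* `phi_g` is the cell-level overdispersion in the "size" parameterization
  (`phi -> inf` recovers Poisson); `sigma2_g` is the variance of the
  per-sample random intercept on the log scale.

The marginal likelihood integrates `u_{g,s}` out per sample.  We use the
Laplace approximation refined by adaptive Gauss–Hermite quadrature centred
and scaled at the Laplace mode; `quad_points = 1` is plain Laplace and the
default of 11 nodes agrees with direct numerical integration to better than
1e-6 on small instances (plain Laplace alone reaches only ~1e-2 at 3
samples x 10 cells, which is why the refinement is the default).  Variance
components are estimated by Nelder–Mead on the profiled marginal
likelihood, with an optional full polish over all parameters; `sigma2`
estimates at the boundary are pinned to 0 and flagged.  When both variance
components are frozen, fitting reduces to a damped, trust-region Newton
solve of the penalized joint objective over `(beta, u)`; standard errors
come from the Schur complement of the joint observed information, which is
exactly the curvature of the Laplace marginal at fixed variance components.

Stage 0 ("overdispersion estimation") fits the model without the state
covariate for every gene detected in at least 10% of cells (configurable)
and freezes `(sigma2_g, phi_g)` for the later stages, matching the
two-stage structure of the overall procedure.  Per-gene ML variance
components carry the usual downward bias from estimated fixed effects;
recovery tests therefore use cohorts with enough samples (60 x 60 cells)
where the median estimates land within 20% of truth.

## Binary latent-state factorization

The dominant binary axis of variation of a cell subset — conceptually the
top principal component, but binary and defined inside the NB mixed model —
is estimated by alternating (EM-style) maximization of an evidence lower
bound over per-gene parameters and the per-cell posterior `q_i = P(z_i=1)`:

* **E-step** — `logit q_i = logit(pi) + sum_g [ll_g(y_gi | z=1) -
  ll_g(y_gi | z=0)]`, accumulated in the log domain and conditioning on the
  empirical-Bayes modes of the sample intercepts (re-integrating per
  candidate state would be intractable per cell; the quadrature oracle
  bounds the approximation error of the mode-conditioning on small
  instances).
* **M-step** — each gene is refit with `q` as fractional state membership:
  every cell contributes with weight `q_i` to the `z=1` branch and
  `1 - q_i` to the `z=0` branch of the expanded design; `pi <- mean(q)`.

Both steps increase the same bound, so the objective trace is monotone
non-decreasing up to tolerance and a decrease beyond tolerance raises an
error.  `q` is clamped to `[1e-6, 1 - 1e-6]` and `pi` to `[1e-3, 1 - 1e-3]`
to keep imputation non-degenerate.  Initialization is the sign of the first
principal component of Pearson residuals from the stage-0 fits, plus 3
random restarts by default (best final bound kept; all seeds recorded).
Convergence is declared when the bound changes by less than
`max(tol, 1e-8 |bound|)` with `tol = 1e-4`.  Label switching is resolved by
canonicalizing to `mean(q) <= 0.5`; a flip negates every `gamma_g` and
absorbs it into the intercept, and is idempotent.

## Uncertainty propagation: association and DEG testing

The state estimate carries uncertainty through `q`.  Downstream tests
propagate it by multiple imputation: M = 20 draws `z^(m) ~ Bernoulli(q)`
are analysed separately and pooled with Rubin's rules (a plug-in mode that
uses `q` directly as a continuous covariate is available for comparison).
When `q` is exactly 0/1 the imputations coincide and the pooled result
equals the single fit.

* **Association** — per imputation, a logistic mixed model
  `logit P(z_i=1) = a0 + a1 group_{s(i)} + (sample covariates) + b_s`,
  `b_s ~ N(0, tau^2)`, fit by the same Laplace machinery with the Bernoulli
  family; `a1` is pooled, two-sided p from the t reference with Rubin's
  degrees of freedom.  The biomarker group is 1 iff mregDC/cDC > 0.185.
  Sample-level covariates are included by default but capped (never
  saturating the samples); simulation studies here use the group-only
  model, matching their generative truth in which covariates do not affect
  the state.  Calibration: with a known state the type-I error sits at the
  nominal 0.05; with posterior uncertainty the pooled test becomes
  conservative (a known property of Wald-type MI pooling with a high
  fraction of missing information), never anti-conservative.
* **State DEGs** — per gene and imputation, the NB mixed model is refit
  with `z^(m)` as covariate at the frozen stage-0 overdispersions; pooled
  estimates give two-sided t p-values, Benjamini–Hochberg adjusted across
  genes.  Per-imputation state effects are median-centred across genes
  before pooling (`center_estimates=True`): because the library-size offset
  is the realized total count, a state that up-regulates more mass than it
  down-regulates shifts every gene's apparent log-fold-change by a common
  composition term; centring removes it under the standard
  most-genes-are-null assumption (the same logic as median-of-ratios /
  TMM normalization).  Without centring the null t-statistics on the
  default synthetic cohort are displaced by about -1.2.

## Composition modules, meta-programs, interactions, survival

* **Relative proportions** — subtype cells / parent-type cells per sample;
  a sample without the parent type yields a missing value, never 0.
  Pairwise-complete Pearson correlations (per-pair n recorded; pairs with
  < 3 complete samples or a constant vector are flagged undefined, with
  the reason).  Modules are called by hierarchical clustering on
  `d = 1 - r` (complete linkage by default) cut at a configurable height
  (default 0.9); undefined correlations are imputed to 0 inside the
  clustering only, and modules are numbered by their first subtype's
  column position so labels are deterministic.  Responder/non-responder
  contrasts use the two-sided Wilcoxon rank-sum test per subtype, with
  cohort filters for all / ICI-containing / ICI-only / anti-PD1-treated
  samples, labelling p < 0.1 and judging significance at p < 0.05.
* **Meta-programs** — malignant cells are scored per program as the mean
  gene-centred log-normalized (counts-per-10k, log1p) expression over the
  program's genes present in the matrix; a cell is eligible for a program
  only if it expresses (raw count > 0) at least 25 of its genes, and is
  assigned to the argmax program if the best score reaches 0.03, else NA.
  A "sum of gene activities" would be scale-dependent on program size, so
  the mean is used and recorded.  Ties go to the lexicographically first
  program name and are flagged.  The alternative assignment threshold of
  1.0 is exposed as configuration but 0.03 is the operative default.
* **Ligand–receptor interactions** — per sample, the mean of interaction
  (ligand L, receptor R) from subtype A to B is
  `(mean L in A + mean R in B) / 2` on log-normalized expression, masked
  when either gene is detected in < 10% of its subtype's cells.
  Significance comes from shuffling subtype labels over the sample's
  cells: Monte-Carlo p = `(1 + #{perm >= obs}) / (1 + n_perm)` (add-one, so
  never exactly 0), or exhaustive enumeration of all label arrangements
  for samples of <= 8 cells.  The "significant mean" is the observed mean
  when p < 0.05 and exactly 0 otherwise.  Across samples: an interaction
  is *exclusive* to the focal subtype when significant in >= 3 samples and
  never significant for any comparison subtype with the same partner; it
  is *differential* between two groups when the two-sided rank-sum p on
  the gated means is < 0.05 and the interaction is present (nonzero) in
  strictly more than half of the samples of each group.  Note the presence
  rule deliberately excludes pure on/off patterns, and a 3-vs-3 contrast
  cannot reach p < 0.05 (the exact rank-sum floor is 0.1) — differential
  analyses need at least 4 samples per group.  Multi-subunit complexes are
  out of scope (the catalog holds simple pairs).
* **Survival** — biomarkers are binarized at named thresholds: mregDC/cDC
  > 0.20 for survival splits and > 0.185 for model grouping (both kept as
  separate configuration, no silent unification); the TCF7+/TCF7- CD8
  ratio defaults to a cohort-median split since no fixed threshold is
  established.  Samples without CD8 T cells have a missing ratio and are
  excluded from combined analyses (counted in an exclusion report).  The
  combined stratification emits the 4-level cross and "both-high vs rest".
  Kaplan–Meier curves, k-group log-rank tests and Cox regression (Efron
  ties, two-sided Wald) are delegated to lifelines; a latest-timepoint
  filter keeps one sample per patient (ordering by an explicit timepoint
  column or pre < on < post, ties to the lexicographically last sample id,
  flagged).  ssGSEA scores bulk samples by the rank-weighted
  (`rank^0.25`) in-set vs unweighted out-of-set ECDF difference summed
  over the ranking; rank-based, hence invariant to monotone transforms,
  with optional range normalization recorded in the output metadata.

## The synthetic cohort generator

`simulate_cohort` draws, in order: sample covariates; latent module
factors `f_s ~ N(0, I)`; per-sample subtype compositions from Dirichlet
distributions whose concentrations are multiplied by `exp(loadings' f_s)`
(two planted modules by default — a naive/immune-recruitment axis carrying
mregDC, naive T and naive B subtypes, and a suppression axis carrying
exhausted/regulatory subtypes); cell type/subtype assignments by
multinomial sampling.  The biomarker group is then *defined* from the
realized mregDC/cDC share via the 0.185 rule — the mregDC concentration
baseline is solved so that roughly `p_biomarker_high` (default 0.3) of
samples fall above it — which makes the generator's labels exactly
consistent with what the pipeline computes from cell counts.  Given the
group, the per-cell state is Bernoulli (`pi_high = 0.6` vs `pi_low = 0.1`),
response is drawn (P(R) = 0.6 high vs 0.25 low), and exponential
proportional-hazards PFS/OS times with configurable log hazard ratios and
independent exponential censoring are attached.  Counts follow the NB
mixed model exactly: baseline abundances lognormal and normalized to sum
to one, covariate effects `N(0, 0.1^2)`, 60 of 300 state genes at
`|gamma| ~ U(0.8, 1.2)` with random signs, `sigma2 = 0.25`, `phi = 5`,
lognormal library sizes (mean 2500 molecules), drawn as a gamma–Poisson
mixture.  Every parent type includes a neutral subtype so the sum-to-one
constraint does not force loaded subtypes of one parent into perfect
anticorrelation.  The default sizes (8 samples x 150 cells x 300 genes)
keep a full pipeline run around a minute while leaving recovery
comfortably measurable; recovery studies that need more information
(overdispersion medians, module ARI, combined-biomarker survival) state
their own larger sizes in the tests.

What the generator does **not** emulate: raw reads, doublets, ambient RNA,
batch/chemistry effects, gene–gene correlation beyond the shared state and
sample effects, zero inflation beyond NB sampling, and patient-level
repeated sampling (each sample is its own patient by default).  Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to artefacts the model excludes.

## Numerical choices and limitations

* eta is clipped to [-700, 60] inside the NB family to avoid overflow;
  Newton steps are trust-region capped (inf-norm 3) with step-halving, and
  a line search that cannot improve the objective terminates the solve at
  the current point rather than accepting a bad step.
* Monte-Carlo permutation p-values use the add-one estimator; exhaustive
  enumeration is exact and used automatically for <= 8 cells.
* The logistic mixed model profiles `tau^2` on a bounded log grid
  [-12, 6]; `|alpha| > 15` or non-finite standard errors flag
  quasi-separation, and an association run fails loudly if more than half
  of its imputations fail.
* Rubin pooling uses the standard degrees of freedom
  `(M-1)(1 + W/((1+1/M)B))^2`, with `df = inf` when the between-imputation
  variance vanishes.
* The per-gene t reference for DEGs is normal for large Rubin df; with 8
  samples the sample-level information in the state covariate is limited
  and the test leans on within-sample contrasts.
* Survival machinery is lifelines'; this package adds validation (rank
  deficiency reported with the offending columns, no-event data returning
  an explicit "no events" result) rather than re-deriving estimators.
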