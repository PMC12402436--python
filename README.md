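# tmesf — tumor-microenvironment cell-state factorization

`tmesf` analyses multi-sample single-cell RNA-seq cohorts of solid tumors
in which a sample-level biomarker — here the share of mature regulatory
dendritic cells among conventional dendritic cells (mregDC/cDC) — is
suspected to organize the rest of the tumor microenvironment.  It is aimed
at computational biologists who have a genes × cells count matrix with
cell-type/subtype annotations, per-sample clinical covariates and survival
times, and who want to go beyond per-gene differential expression between
sample groups.

The core method is a **binary latent cell-state factorization under a
negative-binomial mixed model**.  Counts are modelled as

    y_gi ~ NB(mu_gi, phi_g),   Var = mu + mu^2/phi
    log mu_gi = log N_i + x_i' beta_g + gamma_g z_i + u_{g,s(i)},
    u_{g,s} ~ N(0, sigma2_g)

with a log library-size offset, fixed covariates `x_i` (age, sex, tissue,
treatment, mitochondrial/ribosomal fractions), a per-sample random
intercept, and a shared per-cell binary state `z_i` — the dominant binary
axis of expression variation of a cell subset, conceptually a binary top
principal component.  An EM-style alternating maximization returns the
posterior `q_i = P(z_i = 1)`, whose uncertainty is propagated into the two
downstream tests by multiple imputation with Rubin's rules:

* a logistic mixed model testing whether the state is enriched in
  biomarker-high samples (mregDC/cDC > 0.185), and
* per-gene NB mixed-model fits calling state-associated genes with
  two-sided t statistics and Benjamini–Hochberg adjustment.

Around this core the package provides the full pipeline: relative subtype
proportions and their correlation **modules** (pairwise-complete Pearson +
hierarchical clustering), **meta-program assignment** of malignant cells
(max mean-centred gene-set score, with minimum-score and minimum-gene
gates), **biomarker survival** stratification (Kaplan–Meier, log-rank, Cox
with Efron ties, single and combined biomarkers, ssGSEA scoring of bulk
cohorts), **ligand–receptor interaction calls** (per-sample label-shuffling
permutation test with significance-gated means, cross-sample exclusive and
differential aggregation), and a **synthetic cohort generator** with known
ground truth that makes every stage testable without any download.

## Worked example

```python
import numpy as np
from tmesf import (SimulationConfig, simulate_cohort, build_design,
                   estimate_overdispersions, BinaryStateFactorization,
                   test_state_association, state_degs,
                   compute_relative_proportions, SubtypeModuleClustering)

cfg = SimulationConfig(seed=11)          # 8 samples x 150 cells, 300 genes
data, truth = simulate_cohort(cfg)

spec, group, status = build_design(data, np.ones(data.n_cells, dtype=bool))
od = estimate_overdispersions(data.counts, spec)
fac = BinaryStateFactorization(random_state=7).fit(data.counts, spec,
                                                   overdispersions=od)
print(f"prevalence pi = {fac.pi_:.3f}, converged in {fac.result_.n_iter} iterations")

assoc = test_state_association(fac.result_, group, spec, data.sample_meta,
                               n_imputations=20, seed=3, include_covariates=False)
print(f"state ~ mregDC group: log-odds = {assoc.estimate:.2f} "
      f"(SE {assoc.se:.2f}), p = {assoc.p:.2e}")

degs = state_degs(data.counts, spec, fac.result_, n_imputations=20, seed=3)
print(f"{(degs['p_adj'] < 0.05).sum()} state DEGs at BH FDR 0.05 "
      f"out of {len(degs)} genes tested")
```

prints

```
prevalence pi = 0.365, converged in 8 iterations
state ~ mregDC group: log-odds = 2.81 (SE 0.16), p = 5.34e-66
64 state DEGs at BH FDR 0.05 out of 298 genes tested
```

The generator planted a state of prevalence 0.6 in mregDC-high and 0.1 in
mregDC-low samples (true group log-odds 2.60) and 60 state genes among
300; the factorization recovers the state (estimated prevalence 0.365 ≈
the cohort mix of the two prevalences), the association test recovers the
log-odds with a decisive p-value, and the DEG stage calls 64 genes — the
60 planted ones plus a handful of false positives consistent with FDR
0.05.  Adding

```python
table = compute_relative_proportions(data)
modules = SubtypeModuleClustering(cut=0.8).fit(table)
```

recovers the planted proportion-covariance module that links mregDC with
the naive T- and B-cell subtypes.

Cohorts round-trip to plain-text MTX + TSV via `write_cohort`/`read_cohort`,
gene sets via GMT (`read_gmt`), and ligand–receptor catalogs via TSV
(`read_lr_catalog`).

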