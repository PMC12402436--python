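"""Uncertainty-aware association and differential-expression testing.

The latent state's posterior q is propagated by multiple imputation: M
independent draws z ~ Bernoulli(q) are analysed separately — a logistic
mixed model for the state-vs-biomarker-group association, an NB mixed model
per gene for state DEGs — and pooled with Rubin's rules.  A plug-in mode
(z replaced by q as a continuous covariate) is available for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from ._glmm import BernoulliFamily, marginal_loglik, penalized_joint_newton
from .factorization import LatentStateResult
from .nbmm import NBMMSpec, fit_nbmm


@dataclass
class AssociationResult:
    estimate: float          # pooled log-odds of state for group-high vs low
    se: float
    df: float
    p: float
    per_imputation: pd.DataFrame
    tau2: float              # mean random-intercept variance across imputations
    covariates: list[str]
    n_imputations: int
    n_failed: int
    mode: str = "imputation"


def rubin_pool(estimates: np.ndarray, variances: np.ndarray) -> tuple[float, float, float]:
    """Rubin's rules: returns (pooled estimate, pooled SE, degrees of freedom)."""
    estimates = np.asarray(estimates, dtype=float)
    variances = np.asarray(variances, dtype=float)
    m = len(estimates)
    qbar = float(estimates.mean())
    w = float(variances.mean())
    if m == 1:
        return qbar, float(np.sqrt(w)), np.inf
    b = float(estimates.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b <= 0:
        return qbar, float(np.sqrt(w)), np.inf
    df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
    return qbar, float(np.sqrt(t)), df


def sample_covariate_design(
    sample_meta: pd.DataFrame,
    sample_ids: pd.Index,
    group: pd.Series,
    include_covariates: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Per-sample design: intercept + biomarker group (+ sample covariates)."""
    sm = sample_meta.loc[sample_ids]
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(sm)),
        "group": group.loc[sample_ids].to_numpy(dtype=float),
    }
    if include_covariates:
        age = sm["age"].to_numpy(dtype=float)
        sd = age.std()
        cols["age"] = (age - age.mean()) / (sd if sd > 0 else 1.0)
        for cat in ("sex", "tissue", "treatment_state", "treatment_group"):
            values = sm[cat].astype(str).to_numpy()
            for lev in sorted(np.unique(values))[1:]:
                cols[f"{cat}[{lev}]"] = (values == lev).astype(float)
    kept = {k: v for k, v in cols.items() if k == "intercept" or np.ptp(v) > 0}
    # drop collinear columns and never let the fixed part saturate the samples
    final: dict[str, np.ndarray] = {}
    mat = None
    max_cols = max(2, len(sample_ids) - 2)
    for name, v in kept.items():
        if name not in ("intercept", "group") and len(final) >= max_cols:
            continue
        cand = v[:, None] if mat is None else np.column_stack([mat, v])
        if np.linalg.matrix_rank(cand) > (0 if mat is None else np.linalg.matrix_rank(mat)):
            final[name] = v
            mat = cand
    return np.column_stack(list(final.values())), list(final)


def fit_logistic_mixed(
    z: np.ndarray,
    X: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    quad_points: int = 11,
) -> dict:
    """Laplace-ML logistic mixed model with a per-sample random intercept."""
    z = np.asarray(z, dtype=float)
    fam = BernoulliFamily()
    offset = np.zeros(len(z))
    cache = {"init": None}

    def neg_profile(log_tau2):
        tau2 = float(np.exp(log_tau2[0]))
        if tau2 > 1e4:
            return 1e12
        res = penalized_joint_newton(z, X, offset, fam, tau2, codes, n_groups,
                                     init=cache["init"])
        cache["init"] = (res["beta"], res["u"])
        eta_fixed = X @ res["beta"]
        ll, _ = marginal_loglik(z, eta_fixed, fam, tau2, codes, n_groups,
                                quad_points=quad_points, u0=res["u"])
        return -ll if np.isfinite(ll) else 1e12

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = optimize.minimize_scalar(lambda t: neg_profile([t]),
                                       bounds=(-12.0, 6.0), method="bounded",
                                       options={"xatol": 1e-6})
    tau2 = float(np.exp(opt.x))
    if tau2 < 1e-5:
        tau2 = 0.0
    res = penalized_joint_newton(z, X, offset, fam, tau2, codes, n_groups,
                                 init=cache["init"])
    se = np.sqrt(np.diag(res["cov_beta"]))
    separated = bool(np.any(np.abs(res["beta"]) > 15) or np.any(~np.isfinite(se)))
    return {
        "beta": res["beta"], "se": se, "tau2": tau2,
        "loglik": -opt.fun, "converged": res["converged"] and not separated,
        "separated": separated,
    }


def impute_states(q: np.ndarray, n_imputations: int, seed: int) -> np.ndarray:
    """Draw z^(m) ~ Bernoulli(q) for m = 1..M; shape (M, n_cells)."""
    rng = np.random.default_rng(seed)
    return (rng.random((n_imputations, len(q))) < q[None, :]).astype(int)


def test_state_association(
    result: LatentStateResult | np.ndarray,
    group: pd.Series,
    spec: NBMMSpec,
    sample_meta: pd.DataFrame,
    n_imputations: int = 20,
    seed: int = 0,
    include_covariates: bool = True,
    mode: str = "imputation",
) -> AssociationResult:
    """Test whether the latent state is enriched in biomarker-high samples.

    Fits logit P(z_i = 1) = a0 + a1 * group_{s(i)} + sample covariates + b_s,
    b_s ~ N(0, tau^2), per imputation and pools a1 by Rubin's rules.
    """
    q = result.q if isinstance(result, LatentStateResult) else np.asarray(result)
    grp = group.dropna()
    if grp.nunique() < 2:
        raise ValueError("both biomarker groups must be represented")
    keep_samples = pd.Index(grp.index)
    cell_keep = np.isin(spec.sample_ids[spec.groups], keep_samples)
    codes_map = keep_samples.get_indexer(spec.sample_ids[spec.groups][cell_keep])
    Xs, colnames = sample_covariate_design(sample_meta, keep_samples, grp,
                                           include_covariates=include_covariates)
    Xc = Xs[codes_map]
    qk = q[cell_keep]
    j_group = colnames.index("group")

    if mode == "plugin":
        fit = fit_logistic_mixed(qk, Xc, codes_map, len(keep_samples))
        est, se = float(fit["beta"][j_group]), float(fit["se"][j_group])
        p = 2.0 * stats.norm.sf(abs(est / se)) if se > 0 else np.nan
        per = pd.DataFrame({"estimate": [est], "se": [se], "tau2": [fit["tau2"]],
                            "converged": [fit["converged"]]})
        return AssociationResult(est, se, np.inf, float(p), per, fit["tau2"],
                                 colnames, 1, 0, mode="plugin")

    if np.all((qk == 0) | (qk == 1)):
        # no uncertainty: every imputation is identical, pool = single fit
        Z = qk[None, :].astype(int)
        n_imputations = 1
    else:
        Z = impute_states(qk, n_imputations, seed)
    rows = []
    for m in range(n_imputations):
        fit = fit_logistic_mixed(Z[m], Xc, codes_map, len(keep_samples))
        rows.append({"estimate": fit["beta"][j_group], "se": fit["se"][j_group],
                     "tau2": fit["tau2"], "converged": fit["converged"],
                     "separated": fit["separated"]})
    per = pd.DataFrame(rows)
    ok = per["converged"] & np.isfinite(per["se"]) & (per["se"] > 0)
    n_failed = int((~ok).sum())
    if n_failed > n_imputations / 2:
        raise RuntimeError(
            f"{n_failed}/{n_imputations} imputation fits failed (quasi-separation?)"
        )
    est, se, df = rubin_pool(per.loc[ok, "estimate"].to_numpy(),
                             per.loc[ok, "se"].to_numpy() ** 2)
    tstat = est / se if se > 0 else np.nan
    p = 2.0 * (stats.t.sf(abs(tstat), df) if np.isfinite(df) else stats.norm.sf(abs(tstat)))
    return AssociationResult(float(est), float(se), float(df), float(p), per,
                             float(per.loc[ok, "tau2"].mean()), colnames,
                             n_imputations, n_failed)


def state_degs(
    counts: np.ndarray,
    spec: NBMMSpec,
    result: LatentStateResult,
    n_imputations: int = 20,
    seed: int = 0,
    center_estimates: bool = True,
) -> pd.DataFrame:
    """Uncertainty-aware state DEGs.

    Per gene, the NB mixed model is refit with the imputed state as a
    covariate at the stage-0 overdispersions; estimates are Rubin-pooled,
    two-sided t p-values are Benjamini-Hochberg adjusted across genes.
    Imputation draws reuse the association stage's generator for the seed.

    ``center_estimates`` subtracts the per-imputation median state effect
    across genes before pooling: the library-size offset (total counts) is
    itself shifted by the state's effect on strongly regulated genes, which
    displaces every gene's log-fold-change by a common composition term;
    centering removes it under the standard assumption that most genes are
    not state-associated.
    """
    q = result.q
    gp = result.gene_params
    gene_idx = result.gene_indices
    Z = impute_states(q, n_imputations, seed)
    if n_imputations == 1:
        Z = result.labels[None, :]
    M, G = Z.shape[0], len(gene_idx)
    est = np.full((M, G), np.nan)
    var = np.full((M, G), np.nan)
    sigma2s = gp["sigma2"].to_numpy(dtype=float)
    phis = gp["phi"].to_numpy(dtype=float)
    for m in range(M):
        state = Z[m].astype(float)
        for g_pos, g in enumerate(gene_idx):
            fit = fit_nbmm(spec, counts[g].astype(float), state=state,
                           phi=phis[g_pos], sigma2=sigma2s[g_pos], quad_points=1)
            if fit.gamma is not None and np.isfinite(fit.gamma) and np.isfinite(fit.se_gamma):
                est[m, g_pos] = fit.gamma
                var[m, g_pos] = fit.se_gamma**2
        if center_estimates:
            est[m] -= np.nanmedian(est[m])
    rows = []
    for g_pos, g in enumerate(gene_idx):
        ok = np.isfinite(est[:, g_pos]) & np.isfinite(var[:, g_pos])
        failed = int(M - ok.sum())
        if not ok.any() or failed > M / 2:
            rows.append({"gene_index": g, "estimate": np.nan, "se": np.nan,
                         "t": np.nan, "p": np.nan, "n_failed": failed})
            continue
        e, se, df = rubin_pool(est[ok, g_pos], var[ok, g_pos])
        tstat = e / se if se > 0 else np.nan
        p = 2.0 * (stats.t.sf(abs(tstat), df) if np.isfinite(df) else stats.norm.sf(abs(tstat)))
        rows.append({"gene_index": g, "estimate": e, "se": se, "t": tstat,
                     "p": p, "n_failed": failed})
    table = pd.DataFrame(rows).set_index("gene_index")
    table["mean_expression"] = counts[gene_idx].mean(axis=1)
    table["fraction_detected"] = (counts[gene_idx] > 0).mean(axis=1)
    padj = np.full(len(table), np.nan)
    ok = table["p"].notna().to_numpy()
    if ok.any():
        padj[ok] = multipletests(table["p"].to_numpy()[ok], method="fdr_bh")[1]
    table["p_adj"] = padj
    return table
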