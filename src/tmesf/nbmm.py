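"""Negative-binomial mixed models for single-cell counts.

Per gene: y_i ~ NB(mu_i, phi) with Var = mu + mu^2/phi and
log mu_i = log N_i + x_i' beta + gamma z_i + u_{s(i)},  u_s ~ N(0, sigma2).
The marginal likelihood integrates the per-sample intercepts out by the
Laplace method with optional adaptive Gauss-Hermite refinement; variance
components are estimated by maximizing this approximate marginal likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from ._glmm import NBFamily, marginal_loglik, penalized_joint_newton
from .simulate import CohortDataset

DEFAULT_QUAD = 11
GROUP_THRESHOLD = 0.185


@dataclass
class NBMMSpec:
    """Design shared across genes for one cell subset."""

    X: np.ndarray              # n_cells x p (includes intercept)
    offset: np.ndarray         # log total counts per cell
    groups: np.ndarray         # sample codes per cell
    sample_ids: pd.Index       # code -> sample id
    colnames: list[str]
    dropped: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self) -> None:
        if len(self.offset) != self.n_cells or len(self.groups) != self.n_cells:
            raise ValueError("offset/groups must align with design rows")
        if not np.all(np.isfinite(self.offset)):
            raise ValueError("offset must be finite")
        counts = np.bincount(self.groups, minlength=self.n_samples)
        if (counts == 0).any():
            raise ValueError("every sample must have at least one cell")


@dataclass
class GeneFit:
    beta: np.ndarray
    se_beta: np.ndarray
    gamma: float | None
    se_gamma: float | None
    sigma2: float
    phi: float
    loglik: float
    converged: bool
    message: str = ""
    colnames: list[str] = field(default_factory=list)
    u: np.ndarray | None = None


def build_design(
    dataset: CohortDataset,
    subset: str | np.ndarray,
    group_threshold: float = GROUP_THRESHOLD,
) -> tuple[NBMMSpec, pd.Series, dict]:
    """Design matrix, per-cell offset/grouping, and the biomarker group vector.

    ``subset`` names a cell type or subtype (or is a boolean cell mask).
    Covariates: intercept, standardized age, dummy-coded sex/tissue/
    treatment_state/treatment_group (first level alphabetically dropped),
    percent_mito and percent_ribo as fractions.  Columns constant across the
    subset are removed and recorded.
    """
    cm = dataset.cell_meta
    if isinstance(subset, str):
        mask = (cm["cell_type"] == subset) | (cm["subtype"] == subset)
    else:
        mask = np.asarray(subset, dtype=bool)
    if mask.sum() == 0:
        raise ValueError(f"subset {subset!r} selects no cells")
    sub = dataset.subset_cells(np.asarray(mask))
    cm = sub.cell_meta
    sm = dataset.sample_meta
    sample_ids = pd.Index(sorted(cm["sample_id"].unique()), name="sample_id")
    if len(sample_ids) < 2:
        raise ValueError("subset must span at least 2 samples")
    per_cell = sm.loc[cm["sample_id"]]

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cm))}
    age = per_cell["age"].to_numpy(dtype=float)
    sd = age.std()
    cols["age"] = (age - age.mean()) / (sd if sd > 0 else 1.0)
    single_level: list[str] = []
    for cat in ("sex", "tissue", "treatment_state", "treatment_group"):
        values = per_cell[cat].astype(str).to_numpy()
        levels = sorted(np.unique(values))
        if len(levels) == 1:
            single_level.append(f"{cat} (constant: {levels[0]})")
        for lev in levels[1:]:
            cols[f"{cat}[{lev}]"] = (values == lev).astype(float)
    cols["percent_mito"] = cm["percent_mito"].to_numpy(dtype=float) / 100.0
    cols["percent_ribo"] = cm["percent_ribo"].to_numpy(dtype=float) / 100.0

    dropped = single_level + [
        name for name, v in cols.items() if name != "intercept" and np.ptp(v) == 0
    ]
    kept = {name: v for name, v in cols.items() if name not in dropped}
    # Greedy rank filter, and a saturation guard: sample-level columns are
    # capped at n_samples - 2 so the random-intercept variance stays
    # identifiable (a saturated sample-level design absorbs all
    # between-sample variation).  Drops are recorded with their reason.
    codes = sample_ids.get_indexer(cm["sample_id"])
    final: dict[str, np.ndarray] = {}
    mat = None
    n_sample_level = 0
    max_sample_level = max(2, len(sample_ids) - 2)
    for name, v in kept.items():
        is_sample_level = all(
            np.ptp(v[codes == s]) == 0 for s in range(len(sample_ids))
        )
        if is_sample_level and n_sample_level >= max_sample_level:
            dropped.append(name + " (saturation guard)")
            continue
        cand = v[:, None] if mat is None else np.column_stack([mat, v])
        if np.linalg.matrix_rank(cand) > (0 if mat is None else np.linalg.matrix_rank(mat)):
            final[name] = v
            mat = cand
            n_sample_level += int(is_sample_level)
        else:
            dropped.append(name + " (collinear)")
    kept = final
    X = np.column_stack(list(kept.values()))

    spec = NBMMSpec(
        X=X,
        offset=np.log(cm["total_counts"].to_numpy(dtype=float)),
        groups=sample_ids.get_indexer(cm["sample_id"]),
        sample_ids=sample_ids,
        colnames=list(kept),
        dropped=dropped,
    )
    spec.validate()

    prop = sm.loc[sample_ids, "mregdc_cdc_proportion"]
    group = pd.Series(np.where(prop > group_threshold, 1, 0), index=sample_ids, name="mregdc_group")
    group[prop.isna()] = pd.NA
    status = {
        "dropped_columns": dropped,
        "n_cells": spec.n_cells,
        "n_samples": spec.n_samples,
        "association_enabled": group.dropna().nunique() > 1,
    }
    return spec, group, status


def _profile_fit(y, X, offset, codes, n_groups, sigma2, phi, init=None, quad_points=DEFAULT_QUAD):
    """Given variance components, maximize over (beta, u) and return marginal loglik."""
    fam = NBFamily(phi=phi)
    res = penalized_joint_newton(y, X, offset, fam, sigma2, codes, n_groups, init=init)
    eta_fixed = offset + X @ res["beta"]
    ll, u = marginal_loglik(y, eta_fixed, fam, sigma2, codes, n_groups,
                            quad_points=quad_points, u0=res["u"])
    return ll, res


def fit_nbmm(
    spec: NBMMSpec,
    y: np.ndarray,
    state: np.ndarray | None = None,
    phi: float | None = None,
    sigma2: float | None = None,
    quad_points: int = DEFAULT_QUAD,
    polish: bool = True,
) -> GeneFit:
    """Fit the NB mixed model for one gene.

    ``state`` (per-cell, binary or fractional) enters as the last design
    column with coefficient gamma.  ``phi``/``sigma2`` may be frozen; free
    components are estimated by approximate marginal ML.  When both are
    frozen the fit is the fast penalized joint-mode (PQL-type) solve with
    Schur-complement standard errors.
    """
    y = np.asarray(y, dtype=float)
    colnames = list(spec.colnames)
    X = spec.X
    if state is not None:
        X = np.column_stack([X, np.asarray(state, dtype=float)])
        colnames = colnames + ["state"]
    n, p = X.shape
    codes, S = spec.groups, spec.n_samples

    if y.sum() == 0:
        return GeneFit(
            beta=np.full(p, np.nan), se_beta=np.full(p, np.nan),
            gamma=np.nan if state is not None else None,
            se_gamma=np.nan if state is not None else None,
            sigma2=0.0, phi=phi or np.nan, loglik=np.nan, converged=False,
            message="degenerate: all counts zero", colnames=colnames,
        )

    both_frozen = phi is not None and sigma2 is not None
    if both_frozen:
        fam = NBFamily(phi=phi)
        res = penalized_joint_newton(y, X, spec.offset, fam, sigma2, codes, S)
        eta_fixed = spec.offset + X @ res["beta"]
        ll, u = marginal_loglik(y, eta_fixed, fam, sigma2, codes, S,
                                quad_points=quad_points, u0=res["u"])
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(res["cov_beta"]))
        return _pack_fit(res["beta"], se, sigma2, phi, ll, res["converged"],
                         colnames, state is not None, res["u"])

    # free variance components: profile (beta, u) inside a 1-2d outer search
    phi0 = phi if phi is not None else _phi_moment_init(y, spec.offset)
    sigma20 = sigma2 if sigma2 is not None else 0.1
    free = []
    if sigma2 is None:
        free.append("sigma2")
    if phi is None:
        free.append("phi")

    beta_cache = {"init": None}

    def unpack(theta):
        vals = {"sigma2": sigma20, "phi": phi0}
        for name, t in zip(free, theta):
            vals[name] = float(np.exp(t))
        return vals["sigma2"], vals["phi"]

    def neg_profile(theta):
        s2, ph = unpack(theta)
        if not np.isfinite(s2) or not np.isfinite(ph) or ph > 1e8 or s2 > 1e4:
            return 1e12
        ll, res = _profile_fit(y, X, spec.offset, codes, S, s2, ph,
                               init=beta_cache["init"], quad_points=quad_points)
        beta_cache["init"] = (res["beta"], res["u"])
        return -ll if np.isfinite(ll) else 1e12

    x0 = np.array([np.log(sigma20) if f == "sigma2" else np.log(phi0) for f in free])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = optimize.minimize(neg_profile, x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6,
                                         "maxiter": 200, "maxfev": 300})
    s2_hat, phi_hat = unpack(opt.x)
    boundary = "sigma2" in free and s2_hat < 1e-6
    if boundary:
        s2_hat = 0.0

    # polish: joint optimization of (beta, free log-variance-components)
    ll, res = _profile_fit(y, X, spec.offset, codes, S, s2_hat, phi_hat,
                           init=beta_cache["init"], quad_points=quad_points)
    beta_hat, u_hat = res["beta"], res["u"]
    if polish and not boundary:
        def neg_full(par):
            b = par[:p]
            s2, ph = unpack(par[p:])
            if ph > 1e8 or s2 > 1e4:
                return 1e12
            eta_fixed = spec.offset + X @ b
            llv, _ = marginal_loglik(y, eta_fixed, NBFamily(phi=ph), s2, codes, S,
                                     quad_points=quad_points, u0=u_hat)
            return -llv if np.isfinite(llv) else 1e12

        par0 = np.concatenate([beta_hat, np.log([s2_hat if f == "sigma2" else phi_hat for f in free])])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            opt2 = optimize.minimize(neg_full, par0, method="Nelder-Mead",
                                     options={"xatol": 1e-7, "fatol": 1e-9,
                                              "maxiter": 4000, "maxfev": 8000})
        if np.isfinite(opt2.fun) and opt2.fun <= -ll + 1e-9:
            beta_hat = opt2.x[:p]
            s2_hat, phi_hat = unpack(opt2.x[p:])
            ll = -opt2.fun
            _, res = _profile_fit(y, X, spec.offset, codes, S, s2_hat, phi_hat,
                                  init=(beta_hat, u_hat), quad_points=quad_points)
            u_hat = res["u"]

    # SEs at (s2_hat, phi_hat) from the Schur complement of the joint Hessian
    fam = NBFamily(phi=phi_hat)
    res_se = penalized_joint_newton(y, X, spec.offset, fam, s2_hat, codes, S,
                                    init=(beta_hat, u_hat))
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(res_se["cov_beta"]))
    msg = "sigma2 at boundary (0)" if boundary else ""
    return _pack_fit(beta_hat, se, s2_hat, phi_hat, ll, bool(opt.success or res["converged"]),
                     colnames, state is not None, u_hat, msg)


def _pack_fit(beta, se, sigma2, phi, ll, converged, colnames, has_state, u, message=""):
    gamma = se_gamma = None
    if has_state:
        gamma, se_gamma = float(beta[-1]), float(se[-1])
    return GeneFit(beta=beta, se_beta=se, gamma=gamma, se_gamma=se_gamma,
                   sigma2=float(sigma2), phi=float(phi), loglik=float(ll),
                   converged=bool(converged), message=message, colnames=colnames, u=u)


def _phi_moment_init(y, offset) -> float:
    # method-of-moments on offset-scaled counts
    rate = y / np.exp(offset)
    m, v = rate.mean(), rate.var()
    if v <= m * 1e-9 or m == 0:
        return 100.0
    phi = m**2 / max(v - m * np.mean(1.0 / np.exp(offset)), 1e-12)
    return float(np.clip(phi, 0.05, 1e4))


def gene_filter(counts: np.ndarray, min_detection: float = 0.1) -> np.ndarray:
    """Genes detected (count > 0) in at least ``min_detection`` of cells."""
    det = (counts > 0).mean(axis=1)
    return det >= min_detection


def estimate_overdispersions(
    counts: np.ndarray,
    spec: NBMMSpec,
    min_detection: float = 0.1,
    quad_points: int = 5,
) -> pd.DataFrame:
    """Stage-0 per-gene fits without the state covariate; (sigma2, phi) are
    frozen afterwards for the factorization stage.

    Returns a DataFrame indexed by gene position with columns sigma2, phi,
    loglik, converged, included, message, and per-covariate beta columns.
    """
    keep = gene_filter(counts, min_detection)
    rows = []
    for g in range(counts.shape[0]):
        if not keep[g]:
            rows.append({"sigma2": np.nan, "phi": np.nan, "loglik": np.nan,
                         "converged": False, "included": False,
                         "message": "filtered: low detection"})
            continue
        fit = fit_nbmm(spec, counts[g], quad_points=quad_points, polish=False)
        rows.append({"sigma2": fit.sigma2, "phi": fit.phi, "loglik": fit.loglik,
                     "converged": fit.converged, "included": np.isfinite(fit.loglik),
                     "message": fit.message,
                     **{f"beta[{c}]": b for c, b in zip(fit.colnames, fit.beta)}})
    return pd.DataFrame(rows)
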