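"""Binary latent cell-state factorization under the NB mixed model.

Finds the single binary per-cell variable that explains the most variability
of the count matrix after adjusting for covariates, the library-size offset
and per-sample random intercepts — conceptually the top (binary) principal
component of the subset.  Estimation is an EM-style alternating maximization
of an evidence lower bound:

* E-step: posterior q_i = P(z_i = 1) from the per-gene NB likelihood ratios
  accumulated in the log domain, conditioning on the empirical-Bayes modes
  of the sample intercepts;
* M-step: per-gene weighted NB mixed-model refit using q as fractional state
  membership (each cell contributes with weight q to the state-1 branch and
  1-q to the state-0 branch), plus the closed-form prevalence update
  pi <- mean(q).

Overdispersions (sigma2_g, phi_g) are estimated once beforehand and frozen.
The bound is monotone non-decreasing up to numerical tolerance; the state
polarity is canonicalized to mean(q) <= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._glmm import NBFamily, penalized_joint_newton
from .nbmm import NBMMSpec, estimate_overdispersions

Q_EPS = 1e-6
PI_EPS = 1e-3


@dataclass
class LatentStateResult:
    """Posterior state probabilities and per-gene state effects."""

    q: np.ndarray                 # per-cell P(z=1 | data)
    labels: np.ndarray            # hard calls 1{q > 0.5}
    pi: float                     # prevalence estimate
    gene_params: pd.DataFrame     # per kept gene: beta..., gamma, sigma2, phi
    gene_indices: np.ndarray      # rows of the count matrix used
    objective_trace: list[float]
    converged: bool
    n_iter: int
    polarity_flipped: bool = False
    seed: int = 0
    eps: float = Q_EPS
    sample_effects: np.ndarray | None = None  # (n_kept_genes, n_samples)

    def __post_init__(self) -> None:
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("q must lie in [0, 1]")


def resolve_polarity(result: LatentStateResult) -> LatentStateResult:
    """Canonicalize label switching: enforce mean(q) <= 0.5.

    Flipping relabels z' = 1 - z, so gamma changes sign and the intercept
    absorbs gamma; idempotent.
    """
    if result.q.mean() <= 0.5:
        return result
    gp = result.gene_params.copy()
    gp["beta[intercept]"] = gp["beta[intercept]"] + gp["gamma"]
    gp["gamma"] = -gp["gamma"]
    return replace(
        result,
        q=1.0 - result.q,
        labels=1 - result.labels,
        pi=1.0 - result.pi,
        gene_params=gp,
        polarity_flipped=not result.polarity_flipped,
    )


class BinaryStateFactorization(BaseEstimator):
    """Estimator for the dominant binary cell state of a cell subset.

    Parameters
    ----------
    max_iter, tol : EM stopping rule (absolute change of the bound).
    n_restarts : random restarts in addition to the PCA-residual init;
        the run with the best final bound is kept.
    min_detection : gene inclusion filter (fraction of cells with count > 0).
    random_state : seed for restarts and any tie-breaking.
    quad_points : Gauss-Hermite nodes for the stage-0 overdispersion fits.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-4, n_restarts: int = 3,
                 min_detection: float = 0.1, random_state: int = 0,
                 quad_points: int = 11):
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.min_detection = min_detection
        self.random_state = random_state
        self.quad_points = quad_points

    # -- internal pieces ---------------------------------------------------

    def _no_state_fits(self, Y, spec, sigma2s, phis):
        """Penalized joint-mode (beta, u) per gene at frozen overdispersions."""
        G = Y.shape[0]
        p = spec.X.shape[1]
        B = np.zeros((G, p))
        U = np.zeros((G, spec.n_samples))
        for g in range(G):
            fam = NBFamily(phi=phis[g])
            res = penalized_joint_newton(Y[g], spec.X, spec.offset, fam,
                                         sigma2s[g], spec.groups, spec.n_samples)
            B[g], U[g] = res["beta"], res["u"]
        return B, U

    def _pca_init(self, Y, spec, B, U, phis, rng):
        eta = spec.offset[None, :] + B @ spec.X.T + U[:, spec.groups]
        mu = np.exp(eta)
        resid = (Y - mu) / np.sqrt(mu + mu**2 / np.asarray(phis)[:, None])
        resid = np.clip(resid, -10, 10)
        resid -= resid.mean(axis=1, keepdims=True)
        # first right singular vector over cells
        _, _, vt = np.linalg.svd(resid, full_matrices=False)
        v = vt[0]
        q0 = np.where(v > np.median(v), 0.8, 0.2)
        return q0

    def _em(self, Y, spec, q, B0, U0, gam0, sigma2s, phis):
        G, n = Y.shape
        S = spec.n_samples
        codes = spec.groups
        X = spec.X
        p = X.shape[1]
        Xe = np.zeros((2 * n, p + 1))
        Xe[:n, :p] = X
        Xe[n:, :p] = X
        Xe[n:, p] = 1.0  # state indicator on the z=1 branch
        ye = np.concatenate([Y[0], Y[0]])  # placeholder, replaced per gene
        codes_e = np.concatenate([codes, codes])
        offset_e = np.concatenate([spec.offset, spec.offset])
        B = np.column_stack([B0, gam0])  # (G, p+1)
        U = U0.copy()
        pi = float(np.clip(q.mean(), PI_EPS, 1 - PI_EPS))
        trace: list[float] = []
        converged = False
        for it in range(self.max_iter):
            # ---- M-step: per-gene weighted refit --------------------------
            w = np.concatenate([1.0 - q, q])
            pen = 0.0
            for g in range(G):
                fam = NBFamily(phi=phis[g])
                ye[:n], ye[n:] = Y[g], Y[g]
                res = penalized_joint_newton(
                    ye, Xe, offset_e, fam, sigma2s[g], codes_e, S,
                    weights=w, init=(B[g], U[g]), max_iter=6,
                )
                B[g], U[g] = res["beta"], res["u"]
                if sigma2s[g] > 0:
                    pen += float(np.sum(U[g] ** 2) / (2.0 * sigma2s[g]))
            pi = float(np.clip(q.mean(), PI_EPS, 1 - PI_EPS))
            # ---- E-step ---------------------------------------------------
            A0 = np.zeros(n)
            D = np.zeros(n)
            for g in range(G):
                fam = NBFamily(phi=phis[g])
                eta0 = spec.offset + X @ B[g, :p] + U[g][codes]
                # gammaln constants cancel in D and are fixed in A0 across
                # iterations, so the kernel keeps the trace comparable
                ll0 = fam.loglik_kernel(Y[g], eta0)
                ll1 = fam.loglik_kernel(Y[g], eta0 + B[g, p])
                A0 += ll0
                D += ll1 - ll0
            logit_q = np.log(pi / (1.0 - pi)) + D
            q = 1.0 / (1.0 + np.exp(-np.clip(logit_q, -500, 500)))
            q = np.clip(q, Q_EPS, 1.0 - Q_EPS)
            # ---- bound ----------------------------------------------------
            elbo = float(
                np.sum(A0 + q * D)
                - pen
                + np.sum(q * np.log(pi) + (1 - q) * np.log(1 - pi))
                - np.sum(q * np.log(q) + (1 - q) * np.log(1 - q))
            )
            trace.append(elbo)
            if it > 0:
                gain = trace[-1] - trace[-2]
                if gain < -10 * self.tol * (1 + abs(trace[-1])):
                    raise RuntimeError(
                        f"EM objective decreased by {-gain:.3g} at iteration {it}; trace={trace}"
                    )
                if abs(gain) < max(self.tol, 1e-8 * abs(trace[-1])):
                    converged = True
                    break
        return q, B, U, pi, trace, converged

    # -- sklearn surface ---------------------------------------------------

    def fit(self, counts: np.ndarray, spec: NBMMSpec,
            overdispersions: pd.DataFrame | None = None):
        """Fit on a genes x cells count matrix and its shared design.

        Sets ``result_`` (a :class:`LatentStateResult`) plus the flat
        attributes ``q_``, ``labels_``, ``pi_``, ``gene_params_``.
        """
        counts = np.asarray(counts)
        if overdispersions is None:
            overdispersions = estimate_overdispersions(
                counts, spec, min_detection=self.min_detection,
                quad_points=self.quad_points,
            )
        ok = overdispersions["included"] & overdispersions["converged"].fillna(False)
        ok &= np.isfinite(overdispersions["phi"]) & (overdispersions["phi"] > 0)
        gene_idx = np.flatnonzero(ok.to_numpy())
        if len(gene_idx) < 2:
            raise ValueError("need at least 2 genes passing the inclusion filter")
        Y = counts[gene_idx].astype(float)
        sigma2s = overdispersions["sigma2"].to_numpy()[gene_idx]
        phis = overdispersions["phi"].to_numpy()[gene_idx]

        rng = np.random.default_rng(self.random_state)
        B0, U0 = self._no_state_fits(Y, spec, sigma2s, phis)
        gam0 = np.zeros(len(gene_idx))

        inits = [self._pca_init(Y, spec, B0, U0, phis, rng)]
        for _ in range(self.n_restarts):
            inits.append(np.where(rng.random(spec.n_cells) < 0.5, 0.8, 0.2))

        best = None
        for q0 in inits:
            q, B, U, pi, trace, conv = self._em(Y, spec, q0.copy(), B0, U0,
                                                gam0, sigma2s, phis)
            if best is None or trace[-1] > best[4][-1]:
                best = (q, B, U, pi, trace, conv)
        q, B, U, pi, trace, conv = best

        p = spec.X.shape[1]
        gp = pd.DataFrame(B[:, :p], columns=[f"beta[{c}]" for c in spec.colnames])
        gp["gamma"] = B[:, p]
        gp["sigma2"] = sigma2s
        gp["phi"] = phis
        gp.index = pd.Index(gene_idx, name="gene_index")

        result = LatentStateResult(
            q=q, labels=(q > 0.5).astype(int), pi=pi, gene_params=gp,
            gene_indices=gene_idx, objective_trace=trace, converged=conv,
            n_iter=len(trace), seed=self.random_state, sample_effects=U,
        )
        result = resolve_polarity(result)
        self.result_ = result
        self.q_ = result.q
        self.labels_ = result.labels
        self.pi_ = result.pi
        self.gene_params_ = result.gene_params
        self.overdispersions_ = overdispersions
        return self

    def fit_transform(self, counts, spec, overdispersions=None):
        return self.fit(counts, spec, overdispersions).q_


def fit_binary_factor(
    counts: np.ndarray,
    spec: NBMMSpec,
    overdispersions: pd.DataFrame | None = None,
    init: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
    n_restarts: int = 3,
) -> LatentStateResult:
    """Functional wrapper over :class:`BinaryStateFactorization`."""
    est = BinaryStateFactorization(max_iter=max_iter, tol=tol, n_restarts=n_restarts,
                                   random_state=seed)
    if init is not None:
        # honour a user-supplied starting posterior by prepending it
        est_inits_patch = np.clip(np.asarray(init, dtype=float), 0.2, 0.8)
        orig = est._pca_init
        est._pca_init = lambda *a, **k: est_inits_patch  # type: ignore[method-assign]
    est.fit(counts, spec, overdispersions=overdispersions)
    return est.result_
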