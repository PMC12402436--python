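"""Shared machinery for GLMMs with a scalar per-sample random intercept.

Marginal likelihood over the random intercepts is approximated per sample by
the Laplace method, optionally refined with adaptive Gauss-Hermite quadrature
centred and scaled at the Laplace mode (``quad_points=1`` is plain Laplace).
Both the negative-binomial family (cell-level overdispersion ``phi``,
Var = mu + mu^2/phi) and the Bernoulli-logit family are supported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import gammaln, logsumexp


@dataclass(frozen=True)
class NBFamily:
    phi: float

    def loglik(self, y, eta):
        return self.loglik_kernel(y, eta) + self.loglik_const(y)

    def loglik_kernel(self, y, eta):
        """log-pmf without the eta-independent gammaln terms (fast path)."""
        phi = self.phi
        eta = np.clip(eta, -700.0, 60.0)
        mu = np.exp(eta)
        return phi * (np.log(phi) - np.log(phi + mu)) + y * (eta - np.log(phi + mu))

    def loglik_const(self, y):
        phi = self.phi
        return gammaln(y + phi) - gammaln(phi) - gammaln(y + 1.0)

    def d1(self, y, eta):
        mu = np.exp(np.clip(eta, -700.0, 60.0))
        return y - (y + self.phi) * mu / (mu + self.phi)

    def d2(self, y, eta):
        # positive curvature: -d^2 loglik / d eta^2
        mu = np.exp(np.clip(eta, -700.0, 60.0))
        return (y + self.phi) * self.phi * mu / (mu + self.phi) ** 2


@dataclass(frozen=True)
class BernoulliFamily:
    def loglik(self, y, eta):
        return y * eta - np.logaddexp(0.0, eta)

    def loglik_kernel(self, y, eta):
        return self.loglik(y, eta)

    def loglik_const(self, y):
        return np.zeros_like(np.asarray(y, dtype=float))

    def d1(self, y, eta):
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500.0, 500.0)))
        return y - p

    def d2(self, y, eta):
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -500.0, 500.0)))
        return np.clip(p * (1.0 - p), 1e-12, None)


def _gsum(v, codes, n_groups):
    return np.bincount(codes, weights=v, minlength=n_groups)


def posterior_mode(y, eta_fixed, family, sigma2, codes, n_groups, weights=None,
                   u0=None, tol=1e-11, max_iter=100):
    """Newton mode of the per-sample random intercepts; returns (u_hat, curvature)."""
    if sigma2 <= 0:
        eta = eta_fixed
        w = 1.0 if weights is None else weights
        h = _gsum(w * family.d2(y, eta), codes, n_groups)
        return np.zeros(n_groups), h + np.inf
    u = np.zeros(n_groups) if u0 is None else u0.copy()
    w = 1.0 if weights is None else weights
    for _ in range(max_iter):
        eta = eta_fixed + u[codes]
        g = _gsum(w * family.d1(y, eta), codes, n_groups) - u / sigma2
        h = _gsum(w * family.d2(y, eta), codes, n_groups) + 1.0 / sigma2
        step = g / h
        np.clip(step, -4.0, 4.0, out=step)
        u += step
        if np.max(np.abs(step)) < tol:
            break
    eta = eta_fixed + u[codes]
    h = _gsum(w * family.d2(y, eta), codes, n_groups) + 1.0 / sigma2
    return u, h


def marginal_loglik(y, eta_fixed, family, sigma2, codes, n_groups,
                    quad_points=11, weights=None, u0=None):
    """Approximate log marginal likelihood, integrating out the random intercepts.

    Returns (total loglik, u_hat).
    """
    w = 1.0 if weights is None else weights
    if sigma2 <= 0:
        ll = float(np.sum(w * family.loglik(y, eta_fixed)))
        return ll, np.zeros(n_groups)
    u, h = posterior_mode(y, eta_fixed, family, sigma2, codes, n_groups,
                          weights=weights, u0=u0)
    const = _gsum(w * family.loglik_const(y), codes, n_groups)

    def f_of_u(uvec):
        eta = eta_fixed + uvec[codes]
        per = const + _gsum(w * family.loglik_kernel(y, eta), codes, n_groups)
        return per - uvec**2 / (2.0 * sigma2) - 0.5 * np.log(2.0 * np.pi * sigma2)

    if quad_points <= 1:
        ll_s = f_of_u(u) + 0.5 * np.log(2.0 * np.pi) - 0.5 * np.log(h)
        return float(ll_s.sum()), u
    x, wts = hermgauss(quad_points)
    tau = 1.0 / np.sqrt(h)
    # adaptive GH centred at the mode: int e^f du ~= sqrt(2) tau sum_k w_k e^{f(u+sqrt2 tau x_k)+x_k^2}
    vals = np.empty((quad_points, n_groups))
    for k in range(quad_points):
        vals[k] = f_of_u(u + np.sqrt(2.0) * tau * x[k]) + x[k] ** 2 + np.log(wts[k])
    ll_s = logsumexp(vals, axis=0) + 0.5 * np.log(2.0) + np.log(tau)
    return float(ll_s.sum()), u


def penalized_joint_newton(y, X, offset, family, sigma2, codes, n_groups,
                           weights=None, init=None, max_iter=100, tol=1e-10):
    """Maximize the penalized (joint-mode) log-likelihood over (beta, u).

    Objective: sum_i w_i l(y_i; o_i + x_i'b + u_{s(i)}) - sum_s u_s^2/(2 sigma2),
    with the eta-independent log-pmf constants omitted (they do not move the
    optimum and are expensive); the returned ``objective`` is therefore only
    comparable across calls with the same (y, weights, family).
    """
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if init is None:
        beta = np.zeros(p)
        # moment start for the intercept keeps Newton in the sane regime
        if p and np.ptp(X[:, 0]) == 0 and X[0, 0] == 1.0:
            rate = np.sum(w * y) / np.sum(w * np.exp(np.clip(offset, -700, 700)))
            beta[0] = np.log(max(rate, 1e-12))
        u = np.zeros(n_groups)
    else:
        beta, u = init[0].copy(), init[1].copy()
    free_u = sigma2 > 0
    if not free_u:
        u = np.zeros(n_groups)

    def objective(beta, u):
        eta = offset + X @ beta + u[codes]
        obj = float(np.sum(w * family.loglik_kernel(y, eta)))
        if free_u:
            obj -= float(np.sum(u**2) / (2.0 * sigma2))
        return obj

    obj = objective(beta, u)
    converged = False
    for _ in range(max_iter):
        eta = offset + X @ beta + u[codes]
        d1 = w * family.d1(y, eta)
        d2 = w * family.d2(y, eta)
        g_b = X.T @ d1
        H_bb = X.T @ (X * d2[:, None])
        if free_u:
            g_u = _gsum(d1, codes, n_groups) - u / sigma2
            H_uu = _gsum(d2, codes, n_groups) + 1.0 / sigma2
            H_bu = np.zeros((p, n_groups))
            for j in range(p):
                H_bu[j] = _gsum(d2 * X[:, j], codes, n_groups)
            # Schur complement solve of the full system
            Hbu_over_Huu = H_bu / H_uu[None, :]
            S_bb = H_bb - Hbu_over_Huu @ H_bu.T
            rhs_b = g_b - Hbu_over_Huu @ g_u
            try:
                step_b = np.linalg.solve(S_bb + 1e-10 * np.eye(p), rhs_b)
            except np.linalg.LinAlgError:
                step_b = np.linalg.lstsq(S_bb, rhs_b, rcond=None)[0]
            step_u = (g_u - H_bu.T @ step_b) / H_uu
        else:
            try:
                step_b = np.linalg.solve(H_bb + 1e-10 * np.eye(p), g_b)
            except np.linalg.LinAlgError:
                step_b = np.linalg.lstsq(H_bb, g_b, rcond=None)[0]
            step_u = np.zeros(n_groups)
        # trust region: log-scale coefficients never need huge moves at once
        norm = np.max(np.abs(step_b)) if p else 0.0
        if norm > 3.0:
            step_b *= 3.0 / norm
            step_u *= 3.0 / norm
        # damped update; never accept a step that lowers the objective
        t = 1.0
        accepted = False
        for _ in range(25):
            nb, nu = beta + t * step_b, u + t * step_u
            new_obj = objective(nb, nu)
            if np.isfinite(new_obj) and new_obj >= obj - 1e-12:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            converged = True  # stuck at a (numerical) stationary point
            break
        beta, u = nb, nu
        gain = new_obj - obj
        obj = new_obj
        if abs(gain) < tol * (1.0 + abs(obj)):
            converged = True
            break

    eta = offset + X @ beta + u[codes]
    d2 = w * family.d2(y, eta)
    H_bb = X.T @ (X * d2[:, None])
    if free_u:
        H_uu = _gsum(d2, codes, n_groups) + 1.0 / sigma2
        H_bu = np.zeros((p, n_groups))
        for j in range(p):
            H_bu[j] = _gsum(d2 * X[:, j], codes, n_groups)
        S_bb = H_bb - (H_bu / H_uu[None, :]) @ H_bu.T
    else:
        S_bb = H_bb
    try:
        cov_b = np.linalg.inv(S_bb)
    except np.linalg.LinAlgError:
        cov_b = np.full((p, p), np.nan)
    return {
        "beta": beta,
        "u": u,
        "objective": obj,
        "cov_beta": cov_b,
        "converged": converged,
    }
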