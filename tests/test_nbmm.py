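import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize

from tmesf._glmm import NBFamily, marginal_loglik
from tmesf.nbmm import (
    NBMMSpec,
    build_design,
    estimate_overdispersions,
    fit_nbmm,
    gene_filter,
)
from tmesf.simulate import SimulationConfig, simulate_cohort


def quad_marginal(y, eta_fixed, phi, sigma2, codes, n_groups):
    """Independent oracle: per-sample 1-d numerical integration (scipy.quad)."""
    fam = NBFamily(phi=phi)
    total = 0.0
    for s in range(n_groups):
        idx = codes == s
        ys, es = y[idx], eta_fixed[idx]

        def logf(u):
            return (np.sum(fam.loglik(ys, es + u))
                    - u**2 / (2 * sigma2) - 0.5 * np.log(2 * np.pi * sigma2))

        g = optimize.minimize_scalar(lambda u: -logf(u), bounds=(-8, 8),
                                     method="bounded", options={"xatol": 1e-10})
        f0 = logf(g.x)
        width = 10 * np.sqrt(sigma2)
        val, _ = integrate.quad(lambda u: np.exp(logf(u) - f0),
                                g.x - width, g.x + width, limit=200)
        total += f0 + np.log(val)
    return total


def _tiny_instance(rng, n_samples=3, max_cells=10):
    cells = rng.integers(4, max_cells + 1)
    codes = np.repeat(np.arange(n_samples), cells)
    n = len(codes)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    offset = np.log(rng.uniform(500, 3000, n))
    beta = np.array([-6.0, 0.3])
    sigma2, phi = 0.25, 5.0
    u = rng.normal(0, np.sqrt(sigma2), n_samples)
    mu = np.exp(offset + X @ beta + u[codes])
    y = rng.poisson(rng.gamma(phi, mu / phi)).astype(float)
    spec = NBMMSpec(X=X, offset=offset, groups=codes,
                    sample_ids=pd.Index([f"S{i}" for i in range(n_samples)]),
                    colnames=["intercept", "x"])
    return spec, y, beta, sigma2, phi


class TestMarginalLikelihood:
    def test_matches_quadrature_oracle_on_tiny_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            spec, y, beta, sigma2, phi = _tiny_instance(rng)
            eta = spec.offset + spec.X @ beta
            fam = NBFamily(phi=phi)
            ll, _ = marginal_loglik(y, eta, fam, sigma2, spec.groups,
                                    spec.n_samples, quad_points=11)
            oracle = quad_marginal(y, eta, phi, sigma2, spec.groups, spec.n_samples)
            assert ll == pytest.approx(oracle, abs=1e-4)

    def test_sigma2_zero_reduces_to_independent_loglik(self):
        rng = np.random.default_rng(1)
        spec, y, beta, _, phi = _tiny_instance(rng)
        eta = spec.offset + spec.X @ beta
        fam = NBFamily(phi=phi)
        ll, u = marginal_loglik(y, eta, fam, 0.0, spec.groups, spec.n_samples)
        assert ll == pytest.approx(float(fam.loglik(y, eta).sum()))
        assert np.all(u == 0)


class TestFitNBMM:
    def test_reduces_to_plain_nb_glm_when_sigma2_zero(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        offset = np.log(rng.uniform(500, 3000, n))
        phi = 5.0
        mu = np.exp(offset + X @ np.array([-6.0, 0.3]))
        y = rng.poisson(rng.gamma(phi, mu / phi)).astype(float)
        spec = NBMMSpec(X=X, offset=offset, groups=np.zeros(n, dtype=int),
                        sample_ids=pd.Index(["S0"]), colnames=["intercept", "x"])
        fit = fit_nbmm(spec, y, phi=phi, sigma2=0.0)
        glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=1 / phi),
                     offset=offset).fit()
        assert np.abs(fit.beta - glm.params).max() < 1e-3

    def test_ml_estimates_match_quadrature_oracle_optimum(self):
        rng = np.random.default_rng(3)
        spec, y, _, _, phi = _tiny_instance(rng)
        fit = fit_nbmm(spec, y, phi=phi)

        def neg_oracle(par):
            b = par[:2]
            s2 = np.exp(par[2])
            return -quad_marginal(y, spec.offset + spec.X @ b, phi, s2,
                                  spec.groups, spec.n_samples)

        x0 = np.concatenate([fit.beta, [np.log(max(fit.sigma2, 1e-6))]])
        opt = optimize.minimize(neg_oracle, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 2000})
        assert np.abs(fit.beta - opt.x[:2]).max() < 1e-3
        assert abs(fit.sigma2 - np.exp(opt.x[2])) < 1e-3

    def test_all_zero_gene_flagged_degenerate(self):
        rng = np.random.default_rng(4)
        spec, y, *_ = _tiny_instance(rng)
        fit = fit_nbmm(spec, np.zeros_like(y), phi=5.0, sigma2=0.1)
        assert not fit.converged
        assert "degenerate" in fit.message


class TestBuildDesign:
    def test_constant_columns_dropped_and_recorded(self, small_cohort):
        data, _ = small_cohort
        data2 = data.subset_cells(np.ones(data.n_cells, dtype=bool))
        data2.sample_meta = data.sample_meta.copy()
        data2.sample_meta["tissue"] = "skin"
        spec, group, status = build_design(data2, np.ones(data2.n_cells, dtype=bool))
        assert not any(c.startswith("tissue") for c in spec.colnames)
        assert any(d.startswith("tissue") for d in spec.dropped)
        assert status["dropped_columns"] == spec.dropped

    def test_group_threshold_boundary(self, small_cohort):
        data, _ = small_cohort
        data2 = data.subset_cells(np.ones(data.n_cells, dtype=bool))
        data2.sample_meta = data.sample_meta.copy()
        sid = data2.sample_meta.index[0]
        data2.sample_meta.loc[sid, "mregdc_cdc_proportion"] = 0.185
        _, group, _ = build_design(data2, np.ones(data2.n_cells, dtype=bool))
        assert group.loc[sid] == 0  # exactly 0.185 is low

    def test_empty_subset_rejected(self, small_cohort):
        data, _ = small_cohort
        with pytest.raises(ValueError, match="no cells"):
            build_design(data, "not-a-subtype")

    def test_offset_is_log_total_counts(self, small_cohort):
        data, _ = small_cohort
        spec, _, _ = build_design(data, "cDC")
        sub = data.cell_meta[(data.cell_meta["cell_type"] == "cDC")]
        assert np.allclose(spec.offset, np.log(sub["total_counts"].to_numpy()))

    def test_sample_level_design_never_saturates(self, default_cohort):
        data, _ = default_cohort
        spec, _, _ = build_design(data, np.ones(data.n_cells, dtype=bool))
        sample_level = [
            c for j, c in enumerate(spec.colnames)
            if all(np.ptp(spec.X[spec.groups == s, j]) == 0
                   for s in range(spec.n_samples))
        ]
        assert len(sample_level) <= spec.n_samples - 2


class TestOverdispersionRecovery:
    def test_filter_keeps_detected_genes(self):
        counts = np.array([[0, 0, 0, 1], [1, 2, 3, 4]])
        assert list(gene_filter(counts, min_detection=0.5)) == [False, True]

    def test_recovers_sigma2_and_phi_at_large_n(self):
        cfg = SimulationConfig(seed=5, n_samples=60, cells_per_sample=60,
                               n_genes=25, n_state_genes=0, gamma_scale=0.0,
                               beta_covariate_sd=0.0)
        data, _ = simulate_cohort(cfg)
        spec, _, _ = build_design(data, np.ones(data.n_cells, dtype=bool))
        od = estimate_overdispersions(data.counts, spec)
        inc = od[od["included"]]
        assert abs(inc["phi"].median() - cfg.phi) / cfg.phi < 0.2
        assert abs(inc["sigma2"].median() - cfg.sigma2) / cfg.sigma2 < 0.2

    def test_poisson_gene_gets_large_phi(self):
        rng = np.random.default_rng(6)
        n_samples, cells = 4, 200
        codes = np.repeat(np.arange(n_samples), cells)
        n = len(codes)
        X = np.ones((n, 1))
        offset = np.log(rng.uniform(500, 3000, n))
        y = rng.poisson(np.exp(offset - 6.0)).astype(float)
        spec = NBMMSpec(X=X, offset=offset, groups=codes,
                        sample_ids=pd.Index([f"S{i}" for i in range(n_samples)]),
                        colnames=["intercept"])
        fit = fit_nbmm(spec, y, sigma2=0.0, polish=False)
        assert 1.0 / fit.phi < 0.05  # overdispersion ~ 0 on the 1/phi scale

    def test_single_sample_pins_sigma2_at_zero(self):
        rng = np.random.default_rng(7)
        n = 200
        X = np.ones((n, 1))
        offset = np.log(rng.uniform(500, 3000, n))
        mu = np.exp(offset - 6.0)
        y = rng.poisson(rng.gamma(5.0, mu / 5.0)).astype(float)
        spec = NBMMSpec(X=X, offset=offset, groups=np.zeros(n, dtype=int),
                        sample_ids=pd.Index(["S0"]), colnames=["intercept"])
        fit = fit_nbmm(spec, y, polish=False)
        assert fit.sigma2 < 1e-3
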