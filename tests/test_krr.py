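"""Gibbs sampler for the kernel Bayesian ridge regression."""

import numpy as np
import pytest

from regionpred.kernel import vanraden_g
from regionpred.krr import (
    MCMCConfig,
    PriorSpec,
    chain_diagnostics,
    genomic_variance_ratio,
    gibbs_krr,
    predict_genetic_values,
    ridge_solution,
)
from regionpred.simulate import simulate_genotypes


def _psd_kernel(n, seed, p_factor=2):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(n, p_factor * n))
    return A @ A.T / (p_factor * n)


class TestConfig:
    def test_full_length_preset_retains_4000_samples(self):
        cfg = MCMCConfig.paper(seed=1)
        assert (cfg.burn_in, cfg.draws, cfg.thin) == (20_000, 40_000, 10)
        assert cfg.n_kept == 4000

    def test_thinning_must_divide_draws(self):
        with pytest.raises(ValueError):
            MCMCConfig(burn_in=100, draws=1000, thin=7)

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(nu=0.0)


class TestGibbs:
    def test_fixed_variances_match_ridge_oracle(self):
        # with degenerate (point-mass) variance priors the stationary mean of
        # alpha is the closed-form ridge estimator
        rng = np.random.default_rng(10)
        n = 30
        K = _psd_kernel(n, 11)
        y = K @ rng.normal(size=n) + rng.normal(0, 0.5, size=n)
        s2a, s2e = 0.8, 0.25
        chain = gibbs_krr(y, K, config=MCMCConfig(2000, 30_000, 3, seed=12),
                          fixed_variances=(s2a, s2e))
        oracle = ridge_solution(K, y, lam=s2e / s2a, mu=float(chain.mu.mean()))
        mcse = chain.alpha.std(axis=0) / np.sqrt(
            np.array([max(_ess_of(chain.alpha[:, j]), 10.0) for j in range(n)]))
        assert np.all(np.abs(chain.alpha_hat - oracle) < 3 * mcse + 1e-3)

    def test_eigen_and_naive_samplers_agree(self):
        rng = np.random.default_rng(13)
        n = 30
        K = _psd_kernel(n, 14)
        y = K @ rng.normal(size=n) + rng.normal(0, 0.5, size=n)
        cfg = dict(priors=PriorSpec(), config=MCMCConfig(1000, 10_000, 5, seed=15))
        a = gibbs_krr(y, K, method="eigen", **cfg)
        cfg["config"] = MCMCConfig(1000, 10_000, 5, seed=16)
        b = gibbs_krr(y, K, method="naive", **cfg)
        assert abs(a.sigma2_e.mean() - b.sigma2_e.mean()) < 0.15 * a.sigma2_e.mean()
        assert abs(a.ghat.mean() - b.ghat.mean()) < 0.1
        assert np.corrcoef(a.ghat, b.ghat)[0, 1] > 0.98

    def test_zero_phenotype_keeps_coefficient_variance_near_prior(self):
        n = 40
        K = _psd_kernel(n, 17)
        chain = gibbs_krr(np.zeros(n), K, config=MCMCConfig(1000, 5000, 5, seed=18))
        assert np.abs(chain.ghat).max() < 0.2
        # proper scaled-inv-chi2 posterior: sigma2_a does not collapse to 0
        assert chain.sigma2_a.min() > 1e-4
        assert 0.05 < np.median(chain.sigma2_a) < 5.0

    def test_seed_determinism(self):
        n = 20
        K = _psd_kernel(n, 19)
        y = np.random.default_rng(20).normal(size=n)
        a = gibbs_krr(y, K, config=MCMCConfig(200, 400, 2, seed=21))
        b = gibbs_krr(y, K, config=MCMCConfig(200, 400, 2, seed=21))
        assert np.array_equal(a.alpha, b.alpha)
        assert np.array_equal(a.sigma2_e, b.sigma2_e)

    def test_invalid_inputs_rejected(self):
        n = 10
        K = _psd_kernel(n, 22)
        y = np.zeros(n)
        with pytest.raises(ValueError):
            gibbs_krr(y, K + np.triu(np.ones((n, n)), 1))
        with pytest.raises(ValueError):
            gibbs_krr(np.r_[y[:-1], np.nan], K)


class TestPrediction:
    def test_trivial_and_hand_worked_products(self):
        assert np.all(predict_genetic_values(np.eye(3), np.zeros(3)) == 0)
        a = np.array([1.0, -2.0, 0.5])
        assert np.allclose(predict_genetic_values(np.eye(3), a), a)
        K_rows = np.array([[1.0, 0.0, 2.0], [0.5, 1.0, 0.0], [0.0, 3.0, 1.0]])
        expected = np.array([1.0 * 1 + 2.0 * 0.5, 0.5 - 2.0, -6.0 + 0.5])
        assert np.allclose(predict_genetic_values(K_rows, a), expected)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            predict_genetic_values(np.eye(3), np.zeros(4))


class TestVarianceRatio:
    def test_huge_residual_variance_drives_ratio_to_zero(self):
        from regionpred.krr import PosteriorChain

        m = 200
        chain = PosteriorChain(
            mu=np.zeros(m), alpha=np.zeros((m, 5)),
            sigma2_e=np.full(m, 1e6), sigma2_a=np.ones(m),
            var_g_samples=np.full(m, 0.5), ghat=np.zeros(5),
            config=MCMCConfig(100, 200, 1, seed=0))
        assert genomic_variance_ratio(chain)["mean"] < 1e-5

    def test_noise_free_signal_drives_ratio_to_one(self):
        # n large enough that the unit-scale variance priors are dominated
        n = 300
        K = _psd_kernel(n, 23)
        g = K @ np.random.default_rng(24).normal(size=n)
        clean = g / g.std()
        hi = genomic_variance_ratio(gibbs_krr(clean, K,
                                              config=MCMCConfig(1000, 4000, 4, seed=26)))
        assert hi["mean"] > 0.85

    def test_recovery_at_intermediate_heritability(self):
        # additive signal expressed through the kernel itself, h2 = 0.5
        rng = np.random.default_rng(27)
        n = 500
        snp_map = [(f"s{j}", "chr1", j + 1) for j in range(2500)]
        geno = simulate_genotypes(n, snp_map, seed=28)
        K = vanraden_g(geno)
        alpha = rng.normal(size=n)
        g = K.values @ alpha
        g *= np.sqrt(0.5) / g.std()
        y = g + rng.normal(0, np.sqrt(0.5), size=n)
        chain = gibbs_krr(y - y.mean(), K, config=MCMCConfig.reduced(seed=29))
        ratio = genomic_variance_ratio(chain)
        assert 0.4 <= ratio["mean"] <= 0.6


class TestDiagnostics:
    def test_iid_chain_ess_near_n(self):
        x = np.random.default_rng(30).normal(size=1000)
        d = chain_diagnostics({"x": x})["x"]
        assert 700 < d["ess"] <= 1300
        assert abs(d["rhat"] - 1.0) < 0.05

    def test_ar1_chain_ess_matches_analytic(self):
        rho = 0.5
        rng = np.random.default_rng(31)
        x = np.empty(20_000)
        x[0] = rng.normal()
        for t in range(1, len(x)):
            x[t] = rho * x[t - 1] + rng.normal() * np.sqrt(1 - rho ** 2)
        ess = chain_diagnostics({"x": x})["x"]["ess"]
        expected = len(x) * (1 - rho) / (1 + rho)
        assert abs(ess - expected) < 0.25 * expected

    def test_constant_chain_flagged(self):
        d = chain_diagnostics({"x": np.ones(500)})["x"]
        assert np.isnan(d["ess"])

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError):
            chain_diagnostics({"x": np.arange(50.0)})


def _ess_of(x):
    from regionpred.krr import _ess

    return _ess(x)
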