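"""Linear OU-network theory: spectra, timescale densities, correlations."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import ks_2samp

from neurotau import (EigenFamily, LinearNetworkSpec, analytic_correlation,
                      eigen_to_timescales, fit_power_law,
                      network_from_eigenvalues, predicted_exponent,
                      sample_eigenvalues, simulate_linear_network,
                      timescale_density)
from neurotau.nonlinear_network import unit_timescales


class TestEigenFamilies:
    def test_uniform_within_bounds(self):
        fam = EigenFamily("uniform", (0.01, 1.0))
        lam = sample_eigenvalues(fam, 5000, seed=0)
        assert lam.min() >= 0.01 and lam.max() <= 1.0

    def test_semicircle_mean_is_radius(self):
        fam = EigenFamily("semicircle", (1.0,))
        lam = sample_eigenvalues(fam, 100_000, seed=1)
        se = 0.5 / np.sqrt(lam.size)  # SD of semicircle R=1 is 1/2
        assert abs(lam.mean() - 1.0) < 3 * se

    def test_gamma_mean_is_shape(self):
        fam = EigenFamily("gamma", (2.0,))
        lam = sample_eigenvalues(fam, 100_000, seed=2)
        se = np.sqrt(2.0 / lam.size)
        assert abs(lam.mean() - 2.0) < 3 * se

    def test_zeta_values(self):
        assert EigenFamily("uniform", (0.0, 1.0)).zeta == 0.0
        assert EigenFamily("semicircle", (1.0,)).zeta == 0.5
        assert EigenFamily("gamma", (0.5,)).zeta == -0.5
        assert EigenFamily("gamma", (2.0,)).zeta == 1.0

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            EigenFamily("uniform", (1.0, 0.5))
        with pytest.raises(ValueError):
            EigenFamily("semicircle", (-1.0,))
        with pytest.raises(ValueError):
            EigenFamily("pareto", (1.0,))


class TestTimescaleDensity:
    def test_uniform_plugin_form(self):
        """f uniform on (0, 1] gives g(tau) = 1/tau^2 on [1, inf)."""
        g = timescale_density(EigenFamily("uniform", (0.0, 1.0)))
        tau = np.array([1.0, 2.0, 10.0])
        np.testing.assert_allclose(g(tau), 1.0 / tau ** 2)

    @pytest.mark.parametrize("family", [
        EigenFamily("uniform", (0.05, 1.0)),
        EigenFamily("semicircle", (1.0,)),
        EigenFamily("gamma", (2.0,)),
    ])
    def test_mass_conservation(self, family):
        g = timescale_density(family)
        lo, hi = g.support
        mid = max(2 * lo, min(1.0, hi))
        a, _ = quad(lambda t: float(g(t)), lo, mid, limit=400)
        b, _ = quad(lambda t: float(g(t)), mid,
                    hi if np.isfinite(hi) else np.inf, limit=400)
        assert a + b == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_inverse_draws_match(self):
        fam = EigenFamily("uniform", (0.1, 1.0))
        lam = sample_eigenvalues(fam, 100_000, seed=3)
        taus = 1.0 / lam
        g = timescale_density(fam)
        from scipy.integrate import cumulative_trapezoid
        grid = np.linspace(1.0, 10.0, 20_001)
        cdf = np.concatenate([[0.0], cumulative_trapezoid(g(grid), grid)])
        for q, x in zip(cdf[::5000], grid[::5000]):
            emp = np.mean(taus <= x)
            assert abs(emp - q) < 0.01


class TestPredictedExponent:
    @pytest.mark.parametrize("zeta,gamma", [(0.0, 2.0), (0.5, 2.5), (1.0, 3.0)])
    def test_formula(self, zeta, gamma):
        assert predicted_exponent(zeta) == gamma

    def test_nonnormalizable(self):
        with pytest.raises(ValueError):
            predicted_exponent(-1.0)


class TestEigenToTimescales:
    def test_tau_syn_proportionality_exact(self):
        lam = np.random.default_rng(4).uniform(0.1, 1.0, 1000)
        t1 = eigen_to_timescales(lam, tau_syn=1.0)
        t2 = eigen_to_timescales(lam, tau_syn=2.0)
        np.testing.assert_allclose(t2, 2.0 * t1)
        assert np.median(t2) == pytest.approx(2.0 * np.median(t1))

    def test_identity_connectivity_gives_tau_syn(self):
        spec = LinearNetworkSpec(W=np.zeros((5, 5)), g=0.0, tau_syn=0.7)
        lam = np.linalg.eigvalsh(spec.M)
        taus = eigen_to_timescales(lam, tau_syn=0.7)
        np.testing.assert_allclose(taus, 0.7)

    def test_epsilon_caps_longest_timescale(self):
        lam = np.random.default_rng(5).uniform(0.0, 1.0, 2000)
        for eps in (1e-3, 1e-2, 1e-1):
            taus = eigen_to_timescales(lam, tau_syn=1.0, epsilon=eps)
            assert taus.max() <= 1.0 / eps + 1e-9
        # monotone collapse: larger epsilon, shorter max timescale
        t_small = eigen_to_timescales(lam, epsilon=1e-3).max()
        t_large = eigen_to_timescales(lam, epsilon=1e-1).max()
        assert t_large < t_small

    def test_invalid_epsilon(self):
        with pytest.raises(ValueError):
            eigen_to_timescales([0.5, 1.0], epsilon=0.0)

    def test_uniform_edge_tail_matches_theory(self):
        """Edge-of-instability uniform spectrum: exponent within 0.15 of 2."""
        fam = EigenFamily("uniform", (0.0, 1.0))
        lam = sample_eigenvalues(fam, 10_000, seed=6)
        taus = eigen_to_timescales(lam, epsilon=1e-4)
        fit = fit_power_law(taus[taus >= 1.0 / fam.lambda_cutoff],
                            decimation=4)
        assert abs(fit.gamma - predicted_exponent(fam.zeta)) <= 0.15


class TestAnalyticCorrelation:
    def test_single_mode_closed_form(self):
        lam, D = 0.7, 1.3
        for t in (0.0, 0.5, 2.0):
            C = analytic_correlation(np.array([[lam]]), D, t)
            assert C[0, 0] == pytest.approx(D / (2 * lam) * np.exp(-lam * t))

    def test_symmetric_psd_at_zero_lag(self):
        rng = np.random.default_rng(7)
        M = network_from_eigenvalues(rng.uniform(0.5, 2.0, 4), seed=0)
        C0 = analytic_correlation(M, 1.0, 0.0)
        np.testing.assert_allclose(C0, C0.T, atol=1e-10)
        assert np.linalg.eigvalsh(C0).min() > -1e-10

    def test_unstable_matrix_rejected(self):
        with pytest.raises(ValueError):
            analytic_correlation(np.array([[-0.1]]), 1.0, 0.0)

    def test_matches_simulation(self):
        """Eigen-sum correlation matrix vs Euler-Maruyama time averages."""
        rng = np.random.default_rng(8)
        M = network_from_eigenvalues(np.array([0.5, 1.0, 2.0]), seed=1)
        spec = LinearNetworkSpec(W=np.eye(3) - M, g=1.0, tau_syn=1.0,
                                 noise=1.0)
        n_batch = 16
        traces = simulate_linear_network(spec, T=400.0, dt=0.01, seed=2,
                                         n_batch=n_batch)
        burn = 2000
        x = traces[:, :, burn:]
        lag = 50  # 0.5 s
        est = np.einsum("bit,bjt->bij", x[:, :, :-lag], x[:, :, lag:]) \
            / (x.shape[2] - lag)
        C_hat = est.mean(axis=0)
        se = est.std(axis=0) / np.sqrt(n_batch)
        C = analytic_correlation(M, 1.0, 0.5)
        assert np.all(np.abs(C_hat - C) < 3 * se + 0.02)


class TestSimulation:
    def test_noiseless_decay(self):
        spec = LinearNetworkSpec(W=np.zeros((3, 3)), g=0.0, noise=0.0)
        traces = simulate_linear_network(spec, T=5.0, dt=0.01, seed=0)
        assert np.abs(traces[:, :, -1]).max() < 1e-6

    def test_single_unit_stationary_variance(self):
        lam, D, tau_syn = 0.8, 2.0, 1.0
        spec = LinearNetworkSpec(W=np.array([[(1 - lam)]]), g=1.0,
                                 tau_syn=tau_syn, noise=D)
        traces = simulate_linear_network(spec, T=500.0, dt=0.01, seed=3,
                                         n_batch=24)
        x = traces[:, 0, 5000:]
        v = x.var(axis=1)
        target = D / (2 * lam * tau_syn)
        se = v.std() / np.sqrt(v.size)
        assert abs(v.mean() - target) < 3 * se + 0.02 * target

    def test_unstable_spec_rejected(self):
        spec = LinearNetworkSpec(W=np.eye(2) * 2.0, g=1.0)
        with pytest.raises(ValueError, match="lambda_min"):
            simulate_linear_network(spec, T=1.0, dt=0.001)

    def test_fitted_unit_timescales_match_inverse_eigenvalues(self):
        """Single-unit AC timescales track the inverse-eigenvalue sample."""
        hits = 0
        n_seeds = 8
        for s in range(n_seeds):
            rng = np.random.default_rng(100 + s)
            lam = rng.uniform(0.25, 1.0, 40)
            M = network_from_eigenvalues(lam, seed=s)
            spec = LinearNetworkSpec(W=np.eye(40) - M, g=1.0, noise=1.0)
            traces = simulate_linear_network(spec, T=1500.0, dt=0.05,
                                             seed=1000 + s)
            ut = unit_timescales(traces[0, :, 1000:], 0.05, max_lag=200)
            p = ks_2samp(ut.taus, 1.0 / lam).pvalue
            hits += p > 0.05
        assert hits >= int(0.8 * n_seeds)
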