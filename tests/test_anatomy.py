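"""Voxel-feature regression, phase-randomized surrogates, Delta R^2."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from neurotau import (AnatomyRegressionModel, NeuronPlacements, VoxelGrid,
                      baseline_region_model, phase_randomize, reduce_features,
                      surrogate_test, unique_explained_variance)
from neurotau.synthetic import gen_voxel_world


def _grid_from_matrix(X, dims=None):
    X = np.asarray(X, dtype=float)
    n, f = X.shape
    return VoxelGrid(fields=X.reshape(1, 1, n, f))


class TestReduceFeatures:
    def test_variance_ordering_example(self):
        """Orthogonal features with variances (4, 1, 0) -> 2 components."""
        rng = np.random.default_rng(0)
        n = 64
        a = rng.standard_normal(n)
        b = rng.standard_normal(n)
        a = (a - a.mean()) / a.std() * 2.0
        b -= b @ a / (a @ a) * a
        b = (b - b.mean()) / b.std() * 1.0
        X = np.column_stack([a, b, np.zeros(n)])
        reduced = reduce_features(_grid_from_matrix(X), 0.95)
        assert reduced.n_features == 2

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 10)) * rng.uniform(0.5, 3, 10)
        grid = _grid_from_matrix(X)
        reduced = reduce_features(grid, 0.95)
        Xc = X - X.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc / (X.shape[0] - 1)))[::-1]
        ratios = np.cumsum(evals) / evals.sum()
        k_oracle = int(np.searchsorted(ratios, 0.95) + 1)
        assert reduced.n_features == k_oracle
        retained = np.var(reduced.features, axis=0, ddof=1).sum() / evals.sum()
        assert retained >= 0.95

    def test_full_variance_target(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 5))
        reduced = reduce_features(_grid_from_matrix(X), 1.0)
        assert reduced.n_features == 5


class TestRidge:
    def test_noiseless_linear_r2_one(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 3))
        beta = np.array([0.5, -0.2, 0.1])
        tau = 10 ** (X @ beta - 0.5)
        grid = _grid_from_matrix(X)
        place = NeuronPlacements(np.arange(50), np.arange(50), tau)
        res = AnatomyRegressionModel(grid, place, penalty=1e-10,
                                     cv=None).fit()
        assert res.r2_insample == pytest.approx(1.0, abs=1e-6)

    def test_matches_normal_equation_oracle(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        tau = np.array([0.1, 0.3, 0.2])
        alpha = 0.7
        grid = _grid_from_matrix(X)
        place = NeuronPlacements(np.arange(3), np.arange(3), tau)
        res = AnatomyRegressionModel(grid, place, penalty=alpha,
                                     cv=None).fit()
        y = np.log10(tau)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta_oracle = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(2),
                                      Xc.T @ yc)
        np.testing.assert_allclose(res.betas, beta_oracle, atol=1e-8)

    def test_planted_signal_fraction_recovered(self):
        r2s = []
        for s in range(10):
            grid, place, truth = gen_voxel_world(
                dims=(6, 6, 6), n_features=8, signal_beta=0.125,
                noise_sd=0.3, seed=s)
            res = AnatomyRegressionModel(grid, place, penalty=1.0).fit()
            r2s.append(res.r2)
        # planted signal fraction ~0.15: cross-validated R^2 in a band
        assert 0.05 <= np.median(r2s) <= 0.25

    def test_beta_rank_recovery(self):
        """Recovered |beta| ranks planted |beta| across features."""
        rng = np.random.default_rng(9)
        rhos = []
        for s in range(10):
            beta = rng.uniform(-0.3, 0.3, 6)
            grid, place, _ = gen_voxel_world(dims=(6, 6, 6), n_features=6,
                                             signal_beta=beta, noise_sd=0.2,
                                             seed=300 + s)
            res = AnatomyRegressionModel(grid, place, penalty=1.0,
                                         cv=None).fit()
            rhos.append(spearmanr(np.abs(beta), np.abs(res.betas)).statistic)
        assert np.median(rhos) > 0.5


class TestBaseline:
    def test_two_region_means(self):
        place = NeuronPlacements(np.arange(4), np.zeros(4, dtype=int),
                                 np.array([1.0, 1.0, 3.0, 3.0]))
        res = baseline_region_model(["A", "A", "B", "B"], place,
                                    log_transform=False)
        assert res.r2_insample == pytest.approx(1.0, abs=1e-4)

    def test_single_region_explains_nothing(self):
        rng = np.random.default_rng(4)
        place = NeuronPlacements(np.arange(20), np.zeros(20, dtype=int),
                                 rng.uniform(0.1, 1.0, 20))
        res = baseline_region_model(["A"] * 20, place)
        assert res.r2_insample == pytest.approx(0.0, abs=1e-6)

    def test_random_labels_within_null_band(self):
        rng = np.random.default_rng(5)
        tau = rng.uniform(0.1, 1.0, 60)
        place = NeuronPlacements(np.arange(60), np.zeros(60, dtype=int), tau)
        labels = rng.integers(0, 3, 60)
        obs = baseline_region_model(labels, place).r2_insample
        null = [baseline_region_model(rng.permutation(labels), place
                                      ).r2_insample for _ in range(200)]
        assert obs <= np.percentile(null, 99.5)


class TestPhaseRandomization:
    def test_amplitude_spectrum_preserved(self):
        rng = np.random.default_rng(6)
        grid = VoxelGrid(fields=rng.standard_normal((6, 5, 4, 3)))
        surr = phase_randomize(grid, seed=0)
        for a in range(3):
            amp0 = np.abs(np.fft.fftn(grid.fields[..., a]))
            amp1 = np.abs(np.fft.fftn(surr.fields[..., a]))
            np.testing.assert_allclose(amp0, amp1, atol=1e-10)

    def test_mean_preserved(self):
        rng = np.random.default_rng(7)
        grid = VoxelGrid(fields=rng.standard_normal((4, 4, 4, 2)) + 3.0)
        surr = phase_randomize(grid, seed=1)
        np.testing.assert_allclose(surr.features.mean(axis=0),
                                   grid.features.mean(axis=0), atol=1e-10)

    def test_constant_field_unchanged(self):
        grid = VoxelGrid(fields=np.full((4, 4, 4, 1), 2.5))
        surr = phase_randomize(grid, seed=2)
        np.testing.assert_allclose(surr.fields, grid.fields, atol=1e-10)

    def test_autocovariance_preserved(self):
        """Wiener-Khinchin: periodic autocovariance matches the original."""
        grid, _, _ = gen_voxel_world(dims=(8, 8, 8), n_features=1,
                                     smoothness=2.0, seed=8)
        surr = phase_randomize(grid, seed=3)
        def periodic_acov(f):
            F = np.fft.fftn(f - f.mean())
            return np.real(np.fft.ifftn(F * np.conj(F))) / f.size
        np.testing.assert_allclose(periodic_acov(surr.fields[..., 0]),
                                   periodic_acov(grid.fields[..., 0]),
                                   atol=1e-8)


class TestSurrogateTest:
    def test_planted_signal_detected(self):
        hits = 0
        for s in range(10):
            grid, place, _ = gen_voxel_world(dims=(6, 6, 6), n_features=4,
                                             signal_beta=0.25, noise_sd=0.15,
                                             seed=s)
            out = surrogate_test(grid, place, n_surr=60, seed=s, penalty=1.0)
            hits += out["p_value"] < 0.05
        assert hits >= 9

    def test_null_calibration(self):
        """No feature-timescale link: surrogate p spread over (0, 1)."""
        ps = []
        for s in range(12):
            grid, place, _ = gen_voxel_world(dims=(5, 5, 5), n_features=4,
                                             signal_beta=0.0, noise_sd=0.3,
                                             seed=50 + s)
            out = surrogate_test(grid, place, n_surr=40, seed=s, penalty=1.0)
            ps.append(out["p_value"])
        ps = np.asarray(ps)
        assert ps.min() < 0.6 and ps.max() > 0.4  # not degenerate
        assert np.mean(ps < 0.1) <= 0.5

    def test_smoother_fields_widen_surrogate_null(self):
        """With spatially smooth timescales independent of the features,
        the chance-alignment (surrogate) R^2 distribution widens as the
        fields get smoother — the confound the surrogate test controls."""
        sds = []
        for smooth in (0.5, 1.5, 3.0):
            vals = []
            for s in range(3):
                _, place, _ = gen_voxel_world(
                    dims=(6, 6, 6), n_features=3, smoothness=smooth,
                    signal_beta=0.4, noise_sd=0.1, seed=40 + s)
                gridB, _, _ = gen_voxel_world(
                    dims=(6, 6, 6), n_features=3, smoothness=smooth,
                    signal_beta=0.0, seed=940 + s)
                rng = np.random.default_rng(s)
                for _ in range(25):
                    sg = phase_randomize(gridB,
                                         seed=rng.integers(2 ** 31))
                    vals.append(AnatomyRegressionModel(
                        sg, place, penalty=1.0, cv=None).fit().r2)
            sds.append(np.std(vals))
        assert sds[0] < sds[1] < sds[2]

    def test_zero_surrogates_error(self):
        grid, place, _ = gen_voxel_world(dims=(4, 4, 4), n_features=2, seed=0)
        with pytest.raises(ValueError):
            surrogate_test(grid, place, n_surr=0)


class TestUniqueExplainedVariance:
    def test_constant_feature_contributes_nothing(self):
        rng = np.random.default_rng(10)
        X = np.column_stack([rng.standard_normal(60), np.full(60, 1.0)])
        tau = 10 ** (0.4 * X[:, 0] - 0.5 + 0.05 * rng.standard_normal(60))
        grid = _grid_from_matrix(X)
        place = NeuronPlacements(np.arange(60), np.arange(60), tau)
        d = unique_explained_variance(grid, place, 1, seed=0, penalty=0.1,
                                      cv=None)
        assert abs(d) < 0.02

    def test_informative_feature_has_largest_delta(self):
        hits = 0
        for s in range(10):
            grid, place, _ = gen_voxel_world(dims=(6, 6, 6), n_features=6,
                                             signal_beta=0.3, noise_sd=0.15,
                                             seed=100 + s)
            deltas = [unique_explained_variance(grid, place, a, seed=s,
                                                penalty=1.0, cv=None)
                      for a in range(6)]
            hits += int(np.argmax(deltas)) == 0
        assert hits >= 9

    def test_duplicated_features_are_redundant(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(80)
        X = np.column_stack([x, x.copy(), rng.standard_normal(80)])
        tau = 10 ** (0.5 * x - 0.5 + 0.05 * rng.standard_normal(80))
        grid = _grid_from_matrix(X)
        place = NeuronPlacements(np.arange(80), np.arange(80), tau)
        d0 = unique_explained_variance(grid, place, 0, seed=1, penalty=0.1,
                                       cv=None)
        assert d0 < 0.05
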