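"""TV-regularized inversion: OLS oracle, solver behaviour, derived maps
and feature extraction."""

import numpy as np
import pytest

from qusliver.rpltv import (CoefficientMaps, RPLTVSolver, SolverConfig,
                            attenuation_from_cumulative, compute_relative_bsc,
                            design_matrix, extract_features, fit_rpl_tv,
                            per_block_ols)
from qusliver.spectral import LogRatioVolume, ROIWindow
from qusliver.synth import make_ground_truth, simulate_spectra


def _volume(Y, freqs, step_cm=0.056):
    return LogRatioVolume(Y=Y, freq_grid_mhz=freqs, axial_step_cm=step_cm)


class TestPerBlockOLS:
    def test_noiseless_model_recovered_exactly(self, piecewise_truth,
                                               noiseless_volume):
        maps = per_block_ols(noiseless_volume)
        assert np.allclose(maps.delta_b, piecewise_truth.delta_b)
        assert np.allclose(maps.delta_n, piecewise_truth.delta_n, atol=1e-9)

    def test_three_frequencies_interpolate(self):
        freqs = np.array([5.0, 10.0, 15.0])
        X = design_matrix(freqs)
        theta = np.array([0.7, -1.2, 0.05])
        Y = (X @ theta)[:, None, None]
        maps = per_block_ols(_volume(Y, freqs))
        resid = Y[:, 0, 0] - X @ np.array([np.log(maps.delta_b[0, 0]),
                                           maps.delta_n[0, 0],
                                           maps.delta_a[0, 0]])
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_fewer_than_three_frequencies_rejected(self):
        freqs = np.array([5.0, 10.0])
        with pytest.raises(ValueError):
            per_block_ols(_volume(np.zeros((2, 1, 1)), freqs))

    def test_estimator_sd_matches_ols_covariance(self):
        # Monte-Carlo spread of the fitted parameters against the analytic
        # OLS covariance sigma^2 (X'X)^-1
        rng = np.random.default_rng(0)
        freqs = np.linspace(4, 18, 30)
        X = design_matrix(freqs)
        sigma = 0.5
        cov = sigma ** 2 * np.linalg.inv(X.T @ X)
        draws = []
        for _ in range(400):
            Y = (rng.normal(scale=sigma, size=30))[:, None, None]
            m = per_block_ols(_volume(Y, freqs))
            draws.append([np.log(m.delta_b[0, 0]), m.delta_n[0, 0],
                          m.delta_a[0, 0]])
        emp_sd = np.std(draws, axis=0, ddof=1)
        assert np.allclose(emp_sd, np.sqrt(np.diag(cov)), rtol=0.15)


class TestFitRPLTV:
    def test_zero_Y_gives_identity_maps(self):
        freqs = np.linspace(4, 18, 10)
        maps = fit_rpl_tv(_volume(np.zeros((10, 4, 4)), freqs))
        assert np.allclose(maps.delta_b, 1.0, atol=1e-8)
        assert np.allclose(maps.delta_n, 0.0, atol=1e-8)
        assert np.allclose(maps.delta_a, 0.0, atol=1e-8)

    def test_constant_truth_recovered_under_any_mu(self):
        # constant (beta, n, a) maps have zero TV, so the fit is exact for
        # arbitrarily heavy regularization; a requires delta_alpha = 0,
        # since constant nonzero attenuation makes the cumulative map a
        # ramp whose TV is not zero
        truth = make_ground_truth((6, 6), delta_b=3.0, delta_n=-2.0,
                                  delta_alpha=0.0)
        vol = simulate_spectra(truth)
        maps = fit_rpl_tv(vol, SolverConfig(mu_b=10.0, mu_n=1e4, mu_a=1e4))
        assert np.allclose(np.log(maps.delta_b), np.log(3.0), atol=1e-3)
        assert np.allclose(maps.delta_n, -2.0, atol=1e-3)
        assert np.allclose(maps.delta_a, 0.0, atol=1e-3)

    def test_mu_to_zero_limit_is_ols(self, noiseless_volume):
        tv = fit_rpl_tv(noiseless_volume,
                        SolverConfig(mu_b=1e-8, mu_n=1e-8, mu_a=1e-8))
        ols = per_block_ols(noiseless_volume)
        for a, b in [(np.log(tv.delta_b), np.log(ols.delta_b)),
                     (tv.delta_n, ols.delta_n), (tv.delta_a, ols.delta_a)]:
            scale = max(np.abs(b).max(), 1e-2)  # Delta-n is identically 0 here
            assert np.abs(a - b).max() / scale < 1e-4

    def test_objective_non_increasing(self, piecewise_truth):
        vol = simulate_spectra(piecewise_truth, noise_sd=0.5, seed=3)
        maps = fit_rpl_tv(vol)
        obj = maps.objective_history
        assert np.all(np.diff(obj) <= 1e-9 * np.maximum(np.abs(obj[:-1]), 1.0))

    def test_tv_beats_ols_on_noisy_piecewise(self, piecewise_truth):
        vol = simulate_spectra(piecewise_truth, noise_sd=0.5, seed=9)
        tv = fit_rpl_tv(vol)
        ols = per_block_ols(vol)

        def rmse(m):
            return (np.sqrt(np.mean((np.log(m.delta_b)
                                     - np.log(piecewise_truth.delta_b)) ** 2))
                    + np.sqrt(np.mean((m.delta_n
                                       - piecewise_truth.delta_n) ** 2))
                    + np.sqrt(np.mean((m.delta_alpha
                                       - piecewise_truth.delta_alpha) ** 2)))
        assert rmse(tv) < rmse(ols)

    def test_increasing_mu_a_weakly_decreases_tv(self, piecewise_truth):
        vol = simulate_spectra(piecewise_truth, noise_sd=0.5, seed=5)

        def tv_of_a(mu_a):
            m = fit_rpl_tv(vol, SolverConfig(mu_a=mu_a, tol=1e-8))
            gz = np.diff(m.delta_a, axis=0)
            gx = np.diff(m.delta_a, axis=1)
            return np.abs(gz).sum() + np.abs(gx).sum()

        tvs = [tv_of_a(mu) for mu in (1e1, 1e2, 1e3, 1e4)]
        assert all(b <= a * 1.01 for a, b in zip(tvs, tvs[1:]))

    def test_delta_b_positive_by_construction(self, piecewise_truth):
        vol = simulate_spectra(piecewise_truth, noise_sd=2.0, seed=13)
        maps = fit_rpl_tv(vol)
        assert np.all(maps.delta_b > 0)

    def test_nonconvergence_flagged_not_raised(self, piecewise_truth):
        vol = simulate_spectra(piecewise_truth, noise_sd=0.5, seed=1)
        maps = fit_rpl_tv(vol, SolverConfig(max_iterations=2, tol=1e-14))
        assert maps.converged is False

    def test_estimator_interface(self, noiseless_volume, piecewise_truth):
        est = RPLTVSolver(mu_b=1e-8, mu_n=1e-8, mu_a=1e-8)
        est.fit(noiseless_volume)
        assert est.converged_
        assert est.delta_b_.shape == piecewise_truth.shape
        assert est.get_params()["mu_n"] == 1e-8
        stacked = RPLTVSolver().transform(noiseless_volume)
        assert stacked.shape == (4,) + piecewise_truth.shape


class TestDerivedMaps:
    def test_linear_ramp_slope(self):
        z = np.arange(6) * 0.3
        alpha = attenuation_from_cumulative(np.tile(z[:, None], (1, 3)), 1.0)
        assert np.allclose(alpha, 0.3)

    def test_constant_cumulative_gives_zero(self):
        alpha = attenuation_from_cumulative(np.ones((5, 4)), 0.5)
        assert np.allclose(alpha, 0.0)

    def test_cumsum_then_difference_roundtrip(self):
        rng = np.random.default_rng(2)
        alpha_true = rng.uniform(0.0, 1.0, (8, 5))
        step = 0.056
        a = np.cumsum(alpha_true, axis=0) * step
        back = attenuation_from_cumulative(a, step)
        assert np.allclose(back[:-1], alpha_true[1:])   # interior rows

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            attenuation_from_cumulative(np.ones((1, 4)), 0.5)

    def test_relative_bsc_values(self):
        maps = CoefficientMaps(
            delta_b=np.array([[1.0, 2.0]]), delta_n=np.array([[0.0, 1.0]]),
            delta_a=np.zeros((1, 2)), delta_alpha=np.zeros((1, 2)),
            axial_step_cm=0.056)
        bsc = compute_relative_bsc(maps, 11.0)
        assert bsc[0, 0] == pytest.approx(1.0)
        assert bsc[0, 1] == pytest.approx(22.0)

    def test_rayleigh_f4_scaling(self):
        # with dn = 4 (Rayleigh scatterers), doubling f multiplies BSC by 16
        maps = CoefficientMaps(
            delta_b=np.ones((1, 1)), delta_n=np.full((1, 1), 4.0),
            delta_a=np.zeros((1, 1)), delta_alpha=np.zeros((1, 1)),
            axial_step_cm=0.056)
        ratio = compute_relative_bsc(maps, 22.0) / compute_relative_bsc(maps, 11.0)
        assert ratio[0, 0] == pytest.approx(16.0)

    def test_nonpositive_frequency_rejected(self):
        maps = CoefficientMaps(np.ones((1, 1)), np.zeros((1, 1)),
                               np.zeros((1, 1)), np.zeros((1, 1)), 0.056)
        with pytest.raises(ValueError):
            compute_relative_bsc(maps, 0.0)


class TestExtractFeatures:
    def _maps(self, value):
        m = np.full((4, 4), float(value))
        return CoefficientMaps(delta_b=np.exp(m), delta_n=m, delta_a=m,
                               delta_alpha=m, axial_step_cm=0.056)

    def test_identical_frames_equal_single_frame_medians(self):
        maps = self._maps(0.3)
        snr = np.full((4, 4), 1.8)
        f1 = extract_features([maps], [snr])
        f3 = extract_features([maps] * 3, [snr] * 3)
        assert f1.delta_alpha == pytest.approx(f3.delta_alpha)
        assert f3.n_frames == 3
        assert f3.snr == pytest.approx(1.8)

    def test_frame_medians_average(self):
        f = extract_features([self._maps(1.0), self._maps(3.0)],
                             [np.ones((4, 4))] * 2)
        assert f.delta_alpha == pytest.approx(2.0)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            extract_features([self._maps(1.0)], [np.ones((4, 4))],
                             roi=ROIWindow(0, 0, 0, 0))

    def test_roi_median_respects_window(self):
        m = np.zeros((4, 4))
        m[:2] = 5.0
        maps = CoefficientMaps(delta_b=np.exp(m), delta_n=m, delta_a=m,
                               delta_alpha=m, axial_step_cm=0.056)
        f = extract_features([maps], [np.ones((4, 4))],
                             roi=ROIWindow(0, 0, 2, 4))
        assert f.delta_alpha == pytest.approx(5.0)
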