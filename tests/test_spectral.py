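"""Spectral processing: IQ conversion, envelope, block geometry, power
spectra, envelope SNR, log spectral ratio, bandwidth and ROI selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qusliver import spectral
from qusliver.spectral import (RAYLEIGH_SNR, BlockGrid, ROIWindow,
                               SpectrumMap, block_grid,
                               compute_envelope, compute_log_spectral_ratio,
                               compute_power_spectrum_map, compute_snr_map,
                               envelope_snr, fixed_region_from_mm, iq_to_rf,
                               select_roi, usable_bandwidth, wavelength_mm)


def _single_block_grid(shape):
    return BlockGrid(block_axial_px=shape[0], block_lateral_px=shape[1],
                     step_axial_px=shape[0], step_lateral_px=shape[1],
                     origins_axial=np.array([0]), origins_lateral=np.array([0]),
                     wavelength_mm=0.14, axial_spacing_mm=0.014,
                     lateral_spacing_mm=0.014)


class TestIQToRF:
    def test_zero_iq_gives_zero_rf(self):
        rf = iq_to_rf(np.zeros(64, dtype=complex), 10e6, 15e6)
        assert np.all(rf == 0)

    def test_sample_count_times_factor(self):
        rf = iq_to_rf(np.ones(100, dtype=complex), 10e6, 15e6,
                      upsample_factor=8)
        assert rf.shape[0] == 800

    def test_constant_iq_remodulates_to_carrier_tone(self):
        fs, fc, A = 10e6, 15e6, 2.5
        rf = iq_to_rf(np.full(256, A, dtype=complex), fs, fc)
        t = np.arange(rf.size) / (fs * 8)
        assert np.allclose(rf, A * np.cos(2 * np.pi * fc * t), atol=1e-9)

    def test_missing_carrier_rejected(self):
        with pytest.raises(ValueError):
            iq_to_rf(np.ones(8, dtype=complex), 10e6, 0.0)


class TestEnvelope:
    def test_tone_envelope_is_amplitude(self):
        t = np.arange(2048)
        rf = 3.0 * np.cos(2 * np.pi * 0.1 * t)
        env = compute_envelope(rf[:, None])[200:-200]
        assert np.allclose(env, 3.0, rtol=0.01)

    def test_zero_rf(self):
        assert np.all(compute_envelope(np.zeros((64, 4))) == 0)

    def test_speckle_envelope_is_rayleigh(self, homogeneous_rf):
        # the envelope of fully developed speckle has an exactly Rayleigh
        # marginal; subsample to decorrelate before the goodness-of-fit
        from scipy import stats
        env = compute_envelope(homogeneous_rf.samples[0])
        sub = env[100:-100:17, :].ravel()
        scale = np.sqrt(np.mean(sub ** 2) / 2.0)
        _, p = stats.kstest(sub, "rayleigh", args=(0, scale))
        assert p > 0.01


class TestBlockGrid:
    def test_stated_geometry_in_pixels(self):
        g = block_grid((1000, 1000), 0.14, 0.014, 0.014)
        assert g.block_axial_px == 200      # round(20*0.14 / 0.014)
        assert g.step_axial_px == 40        # floor(0.2 * 200)

    def test_physical_block_side(self):
        assert 20 * 0.14 == pytest.approx(2.8)
        assert wavelength_mm(11e6) == pytest.approx(0.14, abs=0.0005)

    def test_frame_of_exactly_one_block(self):
        g = block_grid((200, 200), 0.14, 0.014, 0.014)
        assert g.shape == (1, 1)
        assert g.origins_axial[0] == 0

    def test_frame_smaller_than_block_rejected(self):
        with pytest.raises(ValueError):
            block_grid((100, 100), 0.14, 0.014, 0.014)


class TestPowerSpectrum:
    fs = 100e6

    def _frame_grid(self, frame):
        side = 128
        return BlockGrid(side, side, side, side, np.array([0]), np.array([0]),
                         0.14, 0.02, 0.02)

    def test_tone_peak_location(self):
        t = np.arange(128) / self.fs
        frame = np.cos(2 * np.pi * 20e6 * t)[:, None] * np.ones((1, 128))
        grid = self._frame_grid(frame)
        freqs = np.linspace(4, 40, 73)
        sm = compute_power_spectrum_map(frame, grid, freqs, self.fs)
        assert freqs[np.argmax(sm.spectra[:, 0, 0])] == pytest.approx(20.0,
                                                                      abs=0.5)

    def test_white_noise_flat_within_3db(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(size=(256, 256))
        grid = block_grid((256, 256), 0.14, 0.044, 0.044)  # 64 px blocks
        freqs = np.linspace(4, 18, 30)
        sm = compute_power_spectrum_map(frame, grid, freqs, self.fs)
        mean_spec = sm.spectra.mean(axis=(1, 2))
        assert 10 * np.log10(mean_spec.max() / mean_spec.min()) < 3.0

    def test_power_scales_quadratically(self):
        rng = np.random.default_rng(1)
        frame = rng.normal(size=(128, 128))
        grid = self._frame_grid(frame)
        freqs = np.linspace(4, 18, 15)
        s1 = compute_power_spectrum_map(frame, grid, freqs, self.fs)
        s2 = compute_power_spectrum_map(2 * frame, grid, freqs, self.fs)
        assert np.allclose(s2.spectra, 4 * s1.spectra)

    def test_phase_shift_invariance(self):
        # block periodogram power ignores a frame-wide phase shift of a tone
        t = np.arange(128) / self.fs
        grid = None
        freqs = np.linspace(4, 40, 73)
        specs = []
        for phase in (0.0, 1.3):
            frame = np.cos(2 * np.pi * 20e6 * t + phase)[:, None] \
                * np.ones((1, 128))
            grid = self._frame_grid(frame)
            specs.append(compute_power_spectrum_map(frame, grid, freqs,
                                                    self.fs).spectra)
        # leakage bins far below the peak are phase-sensitive; the peak
        # region carries the power and must not move
        floor = 0.01 * specs[0].max()
        assert np.allclose(specs[0], specs[1], rtol=0.1, atol=floor)

    def test_freq_grid_beyond_nyquist_rejected(self):
        frame = np.zeros((128, 128))
        grid = self._frame_grid(frame)
        with pytest.raises(ValueError):
            compute_power_spectrum_map(frame, grid, np.array([60.0]), self.fs)


class TestSNR:
    def test_two_point_block(self):
        env = np.array([[1.0, 3.0], [1.0, 3.0]])
        snr = compute_snr_map(env, _single_block_grid((2, 2)))
        assert snr.values[0, 0] == pytest.approx(2.0)   # mean 2, pop sd 1

    def test_rayleigh_block(self):
        rng = np.random.default_rng(0)
        env = rng.rayleigh(size=(400, 400))
        snr = compute_snr_map(env, _single_block_grid((400, 400)))
        assert snr.values[0, 0] == pytest.approx(1.91, abs=0.05)

    def test_exponential_envelope_tends_to_one(self):
        rng = np.random.default_rng(0)
        env = rng.exponential(size=(500, 500))
        assert envelope_snr(env) == pytest.approx(1.0, abs=0.02)

    def test_constant_block_flagged_undefined(self):
        snr = compute_snr_map(np.ones((4, 4)), _single_block_grid((4, 4)))
        assert np.isnan(snr.values[0, 0])

    @pytest.mark.parametrize("n", [1000, 16000, 256000])
    def test_rayleigh_snr_convergence(self, n):
        rng = np.random.default_rng(7)
        est = envelope_snr(rng.rayleigh(size=n))
        assert abs(est - RAYLEIGH_SNR) < 5.0 / np.sqrt(n)


class TestLogRatio:
    def _map(self, spectra, freqs):
        grid = _single_block_grid((2, 2))
        shape = (len(freqs),) + (1, 1)
        return SpectrumMap(np.broadcast_to(spectra, shape).copy(), freqs, grid)

    def test_equal_spectra_give_zero(self):
        freqs = np.linspace(4, 18, 5)
        s = self._map(np.ones((5, 1, 1)), freqs)
        assert np.allclose(compute_log_spectral_ratio(s, s).Y, 0.0)

    def test_e_fold_gives_one(self):
        freqs = np.linspace(4, 18, 5)
        r = self._map(np.ones((5, 1, 1)), freqs)
        s = self._map(np.e * np.ones((5, 1, 1)), freqs)
        assert np.allclose(compute_log_spectral_ratio(s, r).Y, 1.0)

    def test_membrane_compensation_adds(self):
        freqs = np.linspace(4, 18, 5)
        s = self._map(np.ones((5, 1, 1)), freqs)
        out = compute_log_spectral_ratio(s, s, t_m=np.e ** 2)
        assert np.allclose(out.Y, 2.0)
        assert out.tm_applied

    def test_zero_reference_rejected(self):
        freqs = np.linspace(4, 18, 5)
        s = self._map(np.ones((5, 1, 1)), freqs)
        r = self._map(np.zeros((5, 1, 1)), freqs)
        with pytest.raises(ValueError):
            compute_log_spectral_ratio(s, r)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        freqs = np.linspace(4, 18, 6)
        a = self._map(rng.uniform(0.1, 5, (6, 1, 1)), freqs)
        b = self._map(rng.uniform(0.1, 5, (6, 1, 1)), freqs)
        ab = compute_log_spectral_ratio(a, b).Y
        ba = compute_log_spectral_ratio(b, a).Y
        assert np.allclose(ab, -ba)


class TestUsableBandwidth:
    def _gaussian_map(self):
        freqs = np.arange(1.0, 20.01, 0.1)
        sigma2 = 5.5 ** 2 / (2 * np.log(100.0))   # -20 dB points at 5 and 16
        spec = np.exp(-((freqs - 10.5) ** 2) / (2 * sigma2))
        return SpectrumMap(spec[:, None, None], freqs,
                           _single_block_grid((2, 2)))

    def test_gaussian_minus_20db_points(self):
        lo, hi = usable_bandwidth(self._gaussian_map())
        assert lo == pytest.approx(5.0, abs=0.15)
        assert hi == pytest.approx(16.0, abs=0.15)

    def test_flat_spectrum_full_band(self):
        freqs = np.arange(1.0, 20.01, 0.5)
        sm = SpectrumMap(np.ones((len(freqs), 1, 1)), freqs,
                         _single_block_grid((2, 2)))
        assert usable_bandwidth(sm) == (4.0, 18.0)

    def test_out_of_band_peak_leaves_empty_band(self):
        freqs = np.arange(1.0, 20.01, 0.5)
        spec = np.where(freqs < 3.0, 1.0, 1e-4)   # all in-band below floor
        sm = SpectrumMap(spec[:, None, None], freqs,
                         _single_block_grid((2, 2)))
        with pytest.raises(ValueError):
            usable_bandwidth(sm)


class TestSelectROI:
    def _snr_map(self, values):
        return spectral.SNRMap(np.asarray(values, dtype=float),
                               _single_block_grid((2, 2)))

    def test_uniform_map_tie_breaks_to_origin(self):
        roi = select_roi(self._snr_map(np.full((8, 8), 1.91)))
        assert (roi.axial0, roi.lateral0) == (0, 0)

    def test_planted_window_found(self):
        vals = np.full((8, 8), 1.2)
        vals[3:7, 2:6] = 1.91
        roi = select_roi(self._snr_map(vals), subroi_shape=(4, 4))
        assert (roi.axial0, roi.lateral0) == (3, 2)

    def test_all_below_target_still_returns_argmin(self, caplog):
        vals = np.full((6, 6), 1.0)
        vals[0:3, 0:3] = 1.5
        import logging
        with caplog.at_level(logging.WARNING, logger="qusliver.spectral"):
            roi = select_roi(self._snr_map(vals), subroi_shape=(3, 3))
        assert (roi.axial0, roi.lateral0) == (0, 0)
        assert any("below the Rayleigh" in r.message for r in caplog.records)

    def test_subroi_larger_than_region_rejected(self):
        with pytest.raises(ValueError):
            select_roi(self._snr_map(np.ones((4, 4))), subroi_shape=(5, 5))

    @pytest.mark.parametrize("shape,sub", [((10, 12), (4, 5)),
                                           ((25, 25), (7, 7)),
                                           ((50, 50), (25, 25))])
    def test_agrees_with_brute_force_scan(self, shape, sub):
        rng = np.random.default_rng(sum(shape))
        vals = rng.uniform(1.0, 2.2, shape)
        vals[rng.uniform(size=shape) < 0.05] = np.nan   # undefined blocks
        roi = select_roi(self._snr_map(vals), subroi_shape=sub)
        best, best_origin = np.inf, None
        for i in range(shape[0] - sub[0] + 1):
            for j in range(shape[1] - sub[1] + 1):
                m = np.nanmean(vals[i:i + sub[0], j:j + sub[1]])
                d = abs(m - RAYLEIGH_SNR)
                if np.isfinite(d) and d < best - 1e-15:
                    best, best_origin = d, (i, j)
        assert (roi.axial0, roi.lateral0) == best_origin

    def test_fixed_region_from_physical_extent(self):
        g = block_grid((1000, 1000), 0.14, 0.014, 0.014)
        region = fixed_region_from_mm(g, axial_mm=8.0, lateral_mm=22.0)
        # 8 mm / (40 px * 0.014 mm) ~ 14 blocks axially
        assert region.n_axial == 14
        assert region.n_lateral > region.n_axial
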