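"""Filtering, modulation index, surrogates and comodulogram behavior."""

import dataclasses
import warnings

import numpy as np
import pytest
from scipy import signal as sps

from neurovasc.pac import (BandGrid, LFPRecording, band_amplitude, band_phase,
                           cohort_mi_summary, comodulogram, modulation_index,
                           preprocess, surrogate_mi, _fir_taps, _zero_phase)
from neurovasc.synthetic import PacSignalConfig, generate_pac_signal


def tone(freq, fs=20_000.0, duration=10.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return LFPRecording(samples=amp * np.cos(2 * np.pi * freq * t), sampling_rate=fs)


class TestPreprocess:
    def test_theta_tone_amplitude_preserved(self):
        rec = preprocess(tone(6.0))
        mid = rec.samples[rec.samples.size // 4: -rec.samples.size // 4]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.01)
        assert rec.sampling_rate == 1000.0

    def test_5khz_tone_attenuated_40db(self):
        rec = tone(5000.0)
        out = preprocess(rec)
        # compare RMS in the central region, upsampled-rate change accounted by RMS
        rms_in = np.sqrt(np.mean(rec.samples**2))
        rms_out = np.sqrt(np.mean(out.samples[500:-500] ** 2))
        assert 20 * np.log10(rms_in / max(rms_out, 1e-300)) > 40

    def test_white_noise_passband_flat_within_1db(self):
        rng = np.random.default_rng(0)
        fs = 20_000.0
        rec = LFPRecording(samples=rng.standard_normal(int(60 * fs)), sampling_rate=fs)
        out = preprocess(rec)
        f_in, p_in = sps.welch(rec.samples, fs=fs, nperseg=40_000)
        f_out, p_out = sps.welch(out.samples, fs=out.sampling_rate, nperseg=2000)
        # decimation keeps per-Hz density; compare band averages below 400 Hz
        lo_in = np.mean(p_in[(f_in > 10) & (f_in < 400)])
        lo_out = np.mean(p_out[(f_out > 10) & (f_out < 400)])
        assert abs(10 * np.log10(lo_out / lo_in)) < 1.0
        assert out.samples.var() < rec.samples.var()

    def test_low_rate_skips_filter_with_warning(self):
        rec = LFPRecording(samples=np.random.default_rng(1).standard_normal(5000),
                           sampling_rate=800.0)
        with pytest.warns(UserWarning, match="low-pass"):
            out = preprocess(rec)
        assert out.sampling_rate == 800.0


class TestZeroPhaseFiltering:
    def test_impulse_response_has_zero_group_delay(self):
        x = np.zeros(4001)
        x[2000] = 1.0
        taps = _fir_taps(30.0, 34.0, 1000.0, x.size)
        y = _zero_phase(x, taps)
        assert np.argmax(np.abs(y)) == 2000

    def test_band_too_narrow_for_record_rejected(self):
        rec = LFPRecording(samples=np.zeros(2000) + np.random.default_rng(0).standard_normal(2000),
                           sampling_rate=1000.0)
        with pytest.raises(ValueError, match="filter length"):
            band_phase(rec, (4.0, 4.1))


class TestBandPhase:
    def test_tone_phase_advances_at_carrier_rate(self):
        fs, dur = 1000.0, 30.0
        t = np.arange(int(dur * fs)) / fs
        rec = LFPRecording(samples=np.cos(2 * np.pi * 6.0 * t), sampling_rate=fs)
        ph, edge = band_phase(rec, (5.5, 6.5))
        valid = np.unwrap(ph[edge:-edge])
        slope = (valid[-1] - valid[0]) / ((valid.size - 1) / fs)
        assert slope == pytest.approx(2 * np.pi * 6.0, rel=0.005)

    def test_negated_signal_phase_shifts_by_pi(self):
        fs = 1000.0
        t = np.arange(20_000) / fs
        x = np.cos(2 * np.pi * 6.0 * t)
        rec_pos = LFPRecording(samples=x, sampling_rate=fs)
        rec_neg = LFPRecording(samples=-x, sampling_rate=fs)
        ph_pos, e = band_phase(rec_pos, (5.5, 6.5))
        ph_neg, _ = band_phase(rec_neg, (5.5, 6.5))
        diff = np.angle(np.exp(1j * (ph_neg - ph_pos)))[e:-e]
        assert np.allclose(np.abs(diff), np.pi, atol=1e-6)

    def test_chirp_phase_matches_instantaneous_frequency(self):
        fs, dur = 1000.0, 60.0
        t = np.arange(int(dur * fs)) / fs
        # slow chirp crossing 6 Hz inside the band
        f0, f1 = 5.6, 6.4
        x = np.cos(2 * np.pi * (f0 * t + (f1 - f0) / (2 * dur) * t**2))
        rec = LFPRecording(samples=x, sampling_rate=fs)
        ph, e = band_phase(rec, (5.0, 7.0))
        inst_f = np.diff(np.unwrap(ph[e:-e])) * fs / (2 * np.pi)
        expected = f0 + (f1 - f0) / dur * t[e:-e - 1]
        assert np.max(np.abs(inst_f - expected)) < 0.1


class TestBandAmplitude:
    def test_tone_envelope_recovers_amplitude(self):
        rec = tone(80.0, fs=1000.0, duration=30.0, amp=2.5)
        am, e = band_amplitude(rec, (78.0, 82.0))
        assert np.mean(am[e:-e]) == pytest.approx(2.5, rel=0.01)

    def test_zero_signal_zero_envelope(self):
        rec = LFPRecording(samples=np.full(20_000, 1e-300), sampling_rate=1000.0)
        am, e = band_amplitude(rec, (78.0, 82.0))
        assert np.max(am) < 1e-12


class TestModulationIndex:
    def test_constant_amplitude_cancels(self):
        phi = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        assert modulation_index(phi, np.ones_like(phi)) < 1e-10

    def test_cosine_modulated_amplitude_gives_half(self):
        phi = np.tile(np.linspace(0, 2 * np.pi, 1200, endpoint=False), 5)
        assert modulation_index(phi, 1 + np.cos(phi)) == pytest.approx(0.5, abs=1e-12)

    def test_one_homogeneous_in_amplitude(self):
        phi = np.tile(np.linspace(0, 2 * np.pi, 1000, endpoint=False), 3)
        a = 1 + np.cos(phi)
        assert modulation_index(phi, 3.7 * a) == pytest.approx(
            3.7 * modulation_index(phi, a), abs=1e-12)

    def test_bounded_by_mean_amplitude(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            phi = rng.uniform(-np.pi, np.pi, 5000)
            a = np.abs(rng.standard_normal(5000))
            assert modulation_index(phi, a) <= a.mean() + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            modulation_index(np.zeros(10), np.zeros(11))


class TestSurrogates:
    def test_identical_seed_identical_surrogates(self):
        rng = np.random.default_rng(3)
        phi = rng.uniform(-np.pi, np.pi, 20_000)
        a = np.abs(rng.standard_normal(20_000))
        s1 = surrogate_mi(phi, a, n_surrogates=50, seed=5)
        s2 = surrogate_mi(phi, a, n_surrogates=50, seed=5)
        np.testing.assert_array_equal(s1, s2)

    def test_coupled_signal_exceeds_all_50_surrogates(self):
        cfg = PacSignalConfig(sampling_rate=1000.0, coupling_depth=0.8,
                              noise_white_sd=0.3, noise_pink_sd=0.3, seed=4)
        rec, _ = generate_pac_signal(cfg)
        ph, e1 = band_phase(rec, (5.0, 7.0))
        am, e2 = band_amplitude(rec, (78.0, 82.0), sideband_pad=7.0)
        e = max(e1, e2)
        sl = slice(e, rec.samples.size - e)
        mi = modulation_index(ph[sl], am[sl])
        surr = surrogate_mi(ph[sl], am[sl], n_surrogates=50, seed=6)
        assert mi > surr.max()

    def test_uncoupled_mi_within_surrogate_bulk(self):
        hits = 0
        n_runs = 20
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            phi = np.angle(sps.hilbert(rng.standard_normal(60_000)))
            a = np.abs(sps.hilbert(rng.standard_normal(60_000)))
            mi = modulation_index(phi, a)
            surr = surrogate_mi(phi, a, n_surrogates=50, seed=seed)
            z = (mi - surr.mean()) / surr.std(ddof=1)
            hits += z < 2
        assert hits >= int(0.9 * n_runs)

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError):
            surrogate_mi(np.zeros(2000), np.ones(2000), n_surrogates=1)


class TestComodulogram:
    def test_band_grid_defaults_cover_declared_ranges(self):
        grid = BandGrid()
        assert grid.phase_bands[0] == (4.0, 5.0) and grid.phase_bands[-1] == (7.0, 8.0)
        assert len(grid.amplitude_bands) == 27
        assert grid.amplitude_bands[0] == (30.0, 34.0)
        assert grid.amplitude_bands[-1] == (134.0, 138.0)

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BandGrid(phase_bands=((4.0, 6.0), (5.0, 7.0)))

    def test_coupled_cell_significant_and_raw_peak_localizes(self, fast_pac_config):
        cfg = dataclasses.replace(fast_pac_config, coupling_depth=0.8)
        rec, _ = generate_pac_signal(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            com = comodulogram(preprocess(rec), seed=1)
        i, j = np.unravel_index(np.argmax(com.raw_mi), com.raw_mi.shape)
        pb, ab = com.grid.phase_bands[i], com.grid.amplitude_bands[j]
        assert pb[0] <= 6.0 <= pb[1] and ab[0] <= 80.0 <= ab[1]
        assert com.significant[i, j]

    def test_fixed_seed_reruns_identical(self, fast_pac_config):
        rec, _ = generate_pac_signal(fast_pac_config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c1 = comodulogram(preprocess(rec), seed=2)
            c2 = comodulogram(preprocess(rec), seed=2)
        np.testing.assert_array_equal(c1.raw_mi, c2.raw_mi)
        np.testing.assert_array_equal(c1.z_mi, c2.z_mi)
        np.testing.assert_array_equal(c1.significant, c2.significant)

    def test_z_invariant_raw_scales_under_amplitude_scaling(self, fast_pac_config):
        rec, _ = generate_pac_signal(fast_pac_config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec_lo = preprocess(rec)
        rec_hi = LFPRecording(samples=3.0 * rec_lo.samples,
                              sampling_rate=rec_lo.sampling_rate)
        c_lo = comodulogram(rec_lo, seed=3)
        c_hi = comodulogram(rec_hi, seed=3)
        np.testing.assert_allclose(c_hi.raw_mi, 3.0 * c_lo.raw_mi, rtol=1e-8)
        np.testing.assert_allclose(c_hi.z_mi, c_lo.z_mi, rtol=0, atol=1e-8)

    def test_sampled_mode_matches_explicit_surrogate_construction(self, fast_pac_config):
        """FFT-based null values equal explicit circular-shift surrogates."""
        rec, _ = generate_pac_signal(fast_pac_config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = preprocess(rec)
        grid = BandGrid(phase_bands=((5.0, 7.0),), amplitude_bands=((78.0, 82.0),))
        com = comodulogram(rec, grid=grid, n_surrogates=10, seed=4,
                           surrogate_lags="sampled", correction="normal")
        ph, e1 = band_phase(rec, (5.0, 7.0))
        am, e2 = band_amplitude(rec, (78.0, 82.0), sideband_pad=7.0)
        e = max(e1, e2)
        sl = slice(e, rec.samples.size - e)
        rng = np.random.default_rng(4)
        surr = surrogate_mi(ph[sl], am[sl], n_surrogates=10, seed=rng)
        z_oracle = (modulation_index(ph[sl], am[sl]) - surr.mean()) / surr.std(ddof=1)
        assert com.z_mi[0, 0] == pytest.approx(z_oracle, rel=1e-9)

    def test_short_recording_rejected(self):
        rec = LFPRecording(samples=np.random.default_rng(0).standard_normal(30_000),
                           sampling_rate=1000.0)
        with pytest.raises(ValueError, match="120"):
            comodulogram(rec)


class TestCohortSummary:
    def _comod(self, fast_pac_config, m, seed):
        cfg = dataclasses.replace(fast_pac_config, coupling_depth=m, seed=seed)
        rec, _ = generate_pac_signal(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return comodulogram(preprocess(rec), seed=seed)

    def test_identical_comodulograms_zero_sem(self, fast_pac_config):
        c = self._comod(fast_pac_config, 0.5, 1)
        out = cohort_mi_summary({"g": [c, c, c]})
        assert out["sem"].iloc[0] == pytest.approx(0.0)

    def test_single_electrode_sem_missing(self, fast_pac_config):
        c = self._comod(fast_pac_config, 0.5, 1)
        out = cohort_mi_summary({"g": [c]})
        assert np.isnan(out["sem"].iloc[0])

    def test_stronger_coupling_cohort_ranks_higher(self, fast_pac_config):
        his = [self._comod(fast_pac_config, 0.7, s) for s in (1, 2)]
        los = [self._comod(fast_pac_config, 0.3, s) for s in (3, 4)]
        out = cohort_mi_summary({"high": his, "low": los}).set_index("group")
        assert out.loc["high", "mean"] > out.loc["low", "mean"]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_mi_summary({"g": []})
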