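"""Stimulus synthesis: tones, FM, ripple noise, clicks, and DSP primitives."""

import numpy as np
import pytest
import scipy.signal as sps

from srmkit.audio import DEFAULT_CONVENTION, AudioBuffer, LevelConvention
from srmkit.signals import (
    ClickSpec,
    FMSpec,
    RippleSpec,
    bandpass_butter,
    fit_sm_depth,
    fit_tm_depth,
    fm_instantaneous_frequency,
    measure_erd,
    measure_instantaneous_frequency,
    modulation_spectrum,
    rms_normalize,
    synth_click,
    synth_fm_tone,
    synth_gap_stimulus,
    synth_ripple_noise,
    synth_tone,
)


class TestTone:
    def test_dominant_frequency_by_zero_crossings(self):
        buf = synth_tone(1000.0, 1000.0, 65.0)
        crossings = np.sum(np.diff(np.signbit(buf.samples)) != 0)
        assert abs(crossings - 2000) <= 2

    def test_level_maps_through_convention(self):
        buf = synth_tone(2000.0, 500.0, 65.0)
        assert buf.rms() == pytest.approx(DEFAULT_CONVENTION.rms_for_spl(65.0), rel=1e-3)

    def test_reference_level_gives_unit_rms(self):
        conv = LevelConvention(spl_at_full_scale_rms=72.0)
        buf = synth_tone(500.0, 500.0, 72.0, conv)
        assert buf.rms() == pytest.approx(1.0, rel=1e-3)

    def test_level_linearity_plus_20_db_is_times_10(self):
        a = synth_tone(1000.0, 200.0, 50.0)
        b = synth_tone(1000.0, 200.0, 70.0)
        assert b.rms() / a.rms() == pytest.approx(10.0, rel=1e-9)

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            synth_tone(30000.0, 100.0, 65.0)


class TestFM:
    def test_depth_convention_500hz_carrier_spans_497_to_503(self):
        buf = synth_fm_tone(FMSpec(500.0, 2.0, 6.0), duration_ms=1000.0)
        f_inst = measure_instantaneous_frequency(buf)
        assert f_inst.max() == pytest.approx(503.0, abs=0.1)
        assert f_inst.min() == pytest.approx(497.0, abs=0.1)

    def test_phase_derivative_matches_closed_form(self):
        spec = FMSpec(500.0, 2.0, 6.0)
        buf = synth_fm_tone(spec, duration_ms=1000.0)
        f_inst = measure_instantaneous_frequency(buf, trim_fraction=0.02)
        n = buf.n_samples - 1
        k = int(n * 0.02)
        t = (np.arange(n)[k : n - k] + 0.5) / buf.rate
        expected = fm_instantaneous_frequency(spec, t)
        assert np.max(np.abs(f_inst - expected)) < 0.1

    def test_zero_depth_is_pure_tone_with_identical_channels(self):
        buf = synth_fm_tone(FMSpec(500.0, 2.0, 0.0))
        np.testing.assert_array_equal(buf.samples[:, 0], buf.samples[:, 1])
        f_inst = measure_instantaneous_frequency(buf, trim_fraction=0.05)
        assert np.allclose(f_inst, 500.0, atol=0.5)

    def test_dichotic_deviations_sum_to_zero(self):
        spec = FMSpec(500.0, 2.0, 6.0, dichotic=True)
        buf = synth_fm_tone(spec, duration_ms=1000.0)
        left = measure_instantaneous_frequency(buf, channel=0)
        right = measure_instantaneous_frequency(buf, channel=1)
        np.testing.assert_allclose((left - 500.0) + (right - 500.0), 0.0, atol=0.2)

    def test_diotic_channels_identical(self):
        buf = synth_fm_tone(FMSpec(480.0, 2.0, 4.0, dichotic=False))
        np.testing.assert_array_equal(buf.samples[:, 0], buf.samples[:, 1])

    def test_depth_exceeding_carrier_rejected(self):
        with pytest.raises(ValueError):
            FMSpec(carrier_hz=100.0, depth_hz=250.0)


class TestRipple:
    def test_tm_envelope_periodic_at_4hz(self):
        spec = RippleSpec(tm_rate_hz=4.0, sm_density_cpo=0.0, depth_m_db=6.0,
                          duration_ms=2000.0)
        buf = synth_ripple_noise(spec, seed=5)
        ms = modulation_spectrum(buf)
        peak = ms.frequency_hz[ms.power.idxmax()]
        assert peak == pytest.approx(4.0, abs=0.5)

    @pytest.mark.parametrize("depth", [1.0, 4.0, 10.0])
    def test_tm_depth_recovered_within_half_db(self, depth):
        spec = RippleSpec(tm_rate_hz=4.0, sm_density_cpo=0.0, depth_m_db=depth,
                          duration_ms=2000.0)
        buf = synth_ripple_noise(spec, seed=42)
        assert fit_tm_depth(buf, 4.0) == pytest.approx(depth, abs=0.5)

    def test_sm_ripple_two_cycles_per_octave(self):
        spec = RippleSpec(tm_rate_hz=0.0, sm_density_cpo=2.0, depth_m_db=6.0,
                          duration_ms=1500.0)
        buf = synth_ripple_noise(spec, seed=7)
        assert fit_sm_depth(buf, 2.0) == pytest.approx(6.0, abs=0.75)

    def test_zero_depth_spectrum_flat_across_band(self):
        spec = RippleSpec(tm_rate_hz=0.0, sm_density_cpo=0.0, depth_m_db=0.0,
                          duration_ms=1500.0)
        buf = synth_ripple_noise(spec, seed=1)
        freqs, power = sps.welch(buf.samples, fs=buf.rate, nperseg=16384)
        edges = 400.0 * 2.0 ** np.arange(0.0, np.log2(20.0), 1.0 / 6.0)
        band_db = [
            10 * np.log10(np.sum(power[(freqs >= a) & (freqs < b)]))
            for a, b in zip(edges[:-1], edges[1:])
        ]
        assert np.std(band_db) < 1.0

    def test_level_and_duration_per_spec(self):
        spec = RippleSpec()
        buf = synth_ripple_noise(spec, seed=0)
        assert buf.duration == pytest.approx(0.5, abs=1e-4)
        assert buf.rms() == pytest.approx(DEFAULT_CONVENTION.rms_for_spl(65.0), rel=1e-9)

    def test_determinism_same_seed_bit_identical(self):
        spec = RippleSpec(duration_ms=200.0)
        a = synth_ripple_noise(spec, seed=9)
        b = synth_ripple_noise(spec, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            RippleSpec(depth_m_db=-1.0)


class TestClicksAndGaps:
    def test_default_click_erd_is_2ms(self):
        assert measure_erd(synth_click()) == pytest.approx(2.0, rel=0.02)

    def test_rectangular_pulse_is_its_own_erd(self):
        rate = 44100
        buf = AudioBuffer(np.concatenate([np.ones(int(0.003 * rate)), np.zeros(100)]),
                          rate)
        assert measure_erd(buf) == pytest.approx(3.0, rel=0.01)

    def test_untruncated_gaussian_sigma_gives_sigma_root_pi(self):
        # ERD of exp(-t^2/(2 sigma^2)) is sigma * sqrt(pi)
        rate = 44100
        sigma = 1.1284e-3
        t = np.arange(-0.02, 0.02, 1 / rate)
        buf = AudioBuffer(np.exp(-(t**2) / (2 * sigma**2)), rate)
        assert measure_erd(buf) == pytest.approx(sigma * np.sqrt(np.pi) * 1000, rel=0.01)

    def test_gap_is_silence_between_truncation_windows(self):
        buf = synth_gap_stimulus(gap_ms=20.0)
        rate = buf.rate
        n_click = int(round(0.004 * rate))
        n_gap = buf.n_samples - 2 * n_click
        assert n_gap == int(round(0.020 * rate))
        assert np.all(buf.samples[n_click : n_click + n_gap] == 0)

    def test_zero_gap_abuts_windows(self):
        buf = synth_gap_stimulus(gap_ms=0.0)
        # total = 2 x envelope window, to within one sample of rounding each
        assert buf.duration == pytest.approx(0.008, abs=2 / buf.rate)

    def test_pe_spl_peak_equals_sinusoid_peak(self):
        buf = synth_click(ClickSpec(peak_level_db_pespl=80.0))
        expected_peak = np.sqrt(2.0) * DEFAULT_CONVENTION.rms_for_spl(80.0)
        assert np.max(np.abs(buf.samples)) == pytest.approx(expected_peak, rel=1e-3)

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            synth_gap_stimulus(gap_ms=-1.0)

    def test_silent_buffer_erd_rejected(self):
        with pytest.raises(ValueError):
            measure_erd(AudioBuffer(np.zeros(100)))


class TestDSPPrimitives:
    def test_bandpass_attenuates_out_of_band_noise(self, rng):
        x = AudioBuffer(rng.standard_normal(2 * 44100), 44100)
        y = bandpass_butter(x, 80.0, 8000.0, 5)
        freqs, px = sps.welch(x.samples, fs=44100, nperseg=4096)
        _, py = sps.welch(y.samples, fs=44100, nperseg=4096)
        hi = freqs >= 16000
        atten_db = 10 * np.log10(np.sum(px[hi]) / np.sum(py[hi]))
        assert atten_db > 40.0

    def test_in_band_tone_level_preserved(self):
        buf = synth_tone(1000.0, 500.0, 65.0)
        out = bandpass_butter(buf, 80.0, 8000.0, 5)
        change_db = 20 * np.log10(out.rms() / buf.rms())
        assert abs(change_db) < 1.0

    def test_invalid_band_rejected(self):
        buf = synth_tone(1000.0, 100.0, 65.0)
        with pytest.raises(ValueError):
            bandpass_butter(buf, 8000.0, 80.0)

    def test_rms_normalize_hits_target_and_preserves_shape(self, rng):
        x = AudioBuffer(rng.standard_normal(1000) * 0.5)
        y = rms_normalize(x, 0.1)
        assert y.rms() == pytest.approx(0.1, rel=1e-12)
        np.testing.assert_allclose(y.samples / x.samples,
                                   y.samples[0] / x.samples[0])

    def test_rms_normalize_scale_factor(self):
        x = AudioBuffer(np.sin(np.linspace(0, 20 * np.pi, 4410)))
        x = AudioBuffer(x.samples * (0.5 / x.rms()))
        y = rms_normalize(x, 0.1)
        np.testing.assert_allclose(y.samples, x.samples * 0.2)

    def test_rms_normalize_identity_when_already_at_target(self):
        x = rms_normalize(AudioBuffer(np.sin(np.linspace(0, 20 * np.pi, 4410))), 0.1)
        y = rms_normalize(x, 0.1)
        np.testing.assert_allclose(y.samples, x.samples, rtol=1e-12)

    def test_silent_input_rejected(self):
        with pytest.raises(ValueError):
            rms_normalize(AudioBuffer(np.zeros(100)))

    def test_modulation_spectrum_flags_unmodulated_noise(self, rng):
        x = AudioBuffer(rng.standard_normal(2 * 44100))
        ms = modulation_spectrum(x)
        # no dominant narrow peak: max bin within 10x of the median power
        assert ms.power.max() < 10 * ms.power.median()

    def test_modulation_spectrum_peaks_at_am_rate(self, rng):
        t = np.arange(2 * 44100) / 44100
        x = AudioBuffer((1 + 0.8 * np.sin(2 * np.pi * 4 * t)) * rng.standard_normal(len(t)))
        ms = modulation_spectrum(x)
        assert ms.frequency_hz[ms.power.idxmax()] == pytest.approx(4.0, abs=0.5)

    def test_modulation_spectrum_rejects_short_input(self):
        with pytest.raises(ValueError):
            modulation_spectrum(AudioBuffer(np.ones(1000)))
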