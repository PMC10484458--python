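"""Spectral core: whitening, periodograms, band peaks and SNR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cagevitals.errors import (
    InsufficientBinsError,
    InsufficientDataError,
    NyquistError,
    ValidationError,
)
from cagevitals.framestore import PixelTrace
from cagevitals.spectral import (
    Band,
    Spectrum,
    band_peak,
    power_spectrum,
    preprocess,
    snr,
    welch_spectrum,
)


def _trace(values, fps=40.0):
    values = np.asarray(values, dtype=np.float64)
    ts = np.round(np.arange(values.size) * 1e6 / fps).astype(np.int64)
    return PixelTrace(values, ts)


def _tone(freq_hz, fps=40.0, n=600, amp=1.0, phase=0.3):
    t = np.arange(n) / fps
    return amp * np.sin(2 * np.pi * freq_hz * t + phase)


class TestPreprocess:
    def test_linear_ramp_becomes_zero(self):
        out = preprocess(_trace(np.linspace(0, 5, 100)))
        assert out.flagged_constant
        np.testing.assert_allclose(out.values, 0.0)

    def test_constant_input_flagged_not_error(self):
        out = preprocess(_trace(np.full(50, 7.0)))
        assert out.flagged_constant
        np.testing.assert_array_equal(out.values, 0.0)

    def test_white_noise_variance_roughly_preserved(self):
        """Unit-variance white input passes through whitening nearly unchanged."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(2000)
            x = (x - x.mean()) / x.std()
            out = preprocess(_trace(x))
            assert abs(out.values.var() - 1.0) < 0.2

    def test_sinusoid_plus_ramp_leaves_single_peak(self):
        x = _tone(2.5) + np.linspace(0, 10, 600)
        spec = power_spectrum(preprocess(_trace(x)), 40.0)
        assert spec.freq_bpm[int(np.argmax(spec.power))] == pytest.approx(150.0, abs=4.0)

    def test_too_few_samples_raises(self):
        with pytest.raises(InsufficientDataError):
            preprocess(_trace(np.arange(5)))

    def test_nonfinite_values_raise(self):
        vals = np.ones(20)
        vals[3] = np.nan
        with pytest.raises(ValidationError):
            preprocess(_trace(vals))


class TestPowerSpectrum:
    def test_forced_sinusoid_peaks_at_150_per_min(self):
        spec = power_spectrum(_trace(_tone(2.5, n=600)), 40.0)
        assert spec.freq_bpm[int(np.argmax(spec.power))] == pytest.approx(150.0, abs=2.0)
        assert spec.nyquist_bpm == pytest.approx(1200.0)
        assert spec.resolution_bpm == pytest.approx(60.0 / 15.0)

    def test_dc_only_input_has_no_power_after_preprocess(self):
        spec = power_spectrum(preprocess(_trace(np.full(100, 3.0))), 40.0)
        assert spec.power.sum() == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_spectrum_is_flat_on_average(self):
        """Monte-Carlo: averaged over 100 seeds no bin exceeds 10x the median."""
        acc = None
        for seed in range(100):
            rng = np.random.default_rng(seed)
            spec = power_spectrum(_trace(rng.standard_normal(600)), 40.0)
            acc = spec.power if acc is None else acc + spec.power
        nondc = acc[1:]
        assert nondc.max() < 10.0 * np.median(nondc)

    def test_excess_timestamp_jitter_rejected(self):
        vals = np.arange(64, dtype=float)
        ts = np.round(np.arange(64) * 25_000).astype(np.int64)
        ts[10] += 10_000  # 40% of the frame interval
        with pytest.raises(ValidationError):
            power_spectrum(PixelTrace(vals, ts), 40.0)

    def test_empty_trace_raises(self):
        with pytest.raises(InsufficientDataError):
            power_spectrum(PixelTrace(np.array([]), np.array([])), 40.0)


class TestBandPeak:
    def _line_spectrum(self, line_bpm, power_value=10.0):
        freq = np.arange(0, 601, 4.0)
        power = np.zeros_like(freq)
        power[int(line_bpm // 4)] = power_value
        return Spectrum(freq, power, window_s=15.0)

    def test_single_line_found(self):
        peak = band_peak(self._line_spectrum(500.0), Band(400, 600))
        assert peak.freq_bpm == 500.0

    def test_tie_breaks_toward_lower_frequency(self):
        freq = np.arange(0, 601, 4.0)
        power = np.zeros_like(freq)
        power[100] = power[112] = 5.0  # 400 and 448 /min
        peak = band_peak(Spectrum(freq, power, 15.0), Band(300, 500))
        assert peak.freq_bpm == 400.0

    def test_band_above_nyquist_raises_with_limit_named(self):
        with pytest.raises(NyquistError, match="600"):
            band_peak(self._line_spectrum(500.0), Band(700, 900))

    def test_respiration_band_peak_on_synthetic_tone(self):
        x = _tone(2.5, n=600) + 0.1 * np.random.default_rng(0).standard_normal(600)
        spec = power_spectrum(preprocess(_trace(x)), 40.0)
        peak = band_peak(spec, Band(30, 400))
        assert peak.freq_bpm == pytest.approx(150.0, abs=4.0)


class TestSnr:
    def test_pure_line_gives_very_large_snr(self):
        freq = np.arange(0, 601, 4.0)
        power = np.zeros_like(freq)
        power[125] = 1.0  # 500 /min
        power += 1e-9
        s = snr(Spectrum(freq, power, 15.0), 500.0, Band(400, 600))
        assert s >= 1e3

    def test_flat_spectrum_gives_snr_one(self):
        freq = np.arange(0, 601, 4.0)
        s = snr(Spectrum(freq, np.ones_like(freq), 15.0), 500.0, Band(400, 600))
        assert s == pytest.approx(1.0)

    def test_band_with_too_few_bins_raises(self):
        freq = np.arange(0, 601, 4.0)
        with pytest.raises(InsufficientBinsError):
            snr(Spectrum(freq, np.ones_like(freq), 15.0), 500.0, Band(490, 510))


class TestProperties:
    @settings(deadline=None, max_examples=30)
    @given(
        seed=st.integers(0, 2**16),
        lo=st.floats(30, 500),
        width=st.floats(50, 400),
    )
    def test_peak_always_within_band_and_nyquist(self, seed, lo, width):
        rng = np.random.default_rng(seed)
        spec = power_spectrum(_trace(rng.standard_normal(400)), 40.0)
        band = Band(lo, min(lo + width, 1200.0))
        peak = band_peak(spec, band)
        assert band.lo_bpm <= peak.freq_bpm <= band.hi_bpm
        assert peak.freq_bpm <= spec.nyquist_bpm

    def test_half_window_estimates_agree(self):
        """Stationary tone: estimates from disjoint halves agree within
        twice the (half-window) frequency resolution."""
        x = _tone(2.5, n=1200) + 0.2 * np.random.default_rng(1).standard_normal(1200)
        halves = []
        for part in (x[:600], x[600:]):
            spec = power_spectrum(preprocess(_trace(part)), 40.0)
            halves.append(band_peak(spec, Band(30, 400)).freq_bpm)
        res_bpm = 60.0 / 15.0
        assert abs(halves[0] - halves[1]) <= 2 * res_bpm

    def test_single_tone_grid_matches_generator_frequency(self):
        """Oracle equivalence: noiseless tones across the band land within
        one bin of the generating frequency."""
        res_bpm = 60.0 / 15.0
        for bpm in np.arange(60, 1141, 90):
            spec = power_spectrum(preprocess(_trace(_tone(bpm / 60.0))), 40.0)
            peak = band_peak(spec, Band(30, 1160))
            assert abs(peak.freq_bpm - bpm) <= res_bpm

    def test_welch_spectrum_has_stable_noise_floor(self):
        rng = np.random.default_rng(2)
        spec = welch_spectrum(_trace(rng.standard_normal(600)), 40.0)
        band = spec.power[1:]
        assert band.max() / np.median(band) < 3.0
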