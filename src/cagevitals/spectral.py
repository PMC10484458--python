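"""Shared signal-analysis core: detrend/whiten, spectra, peak picking, SNR.

Both vital-sign pipelines reduce to the same chain: a scalar trace is
detrended and prewhitened, a one-sided power spectrum is computed, the
in-band maximum is located, and a peak-to-noise-floor ratio quantifies
confidence.  Frequencies are expressed in events/min throughout (beats/min
for cardiac bands, breaths/min for respiratory bands).

Whitening is AR(1) prewhitening by default: the lag-1 autocorrelation rho is
estimated from the (detrended) trace and the filter y[t] - rho*y[t-1] is
applied.  On drift-dominated traces rho -> 1 and the filter approaches first
differencing, suppressing the slow room-wide oscillation; on already-white
traces rho -> 0 and the filter approaches identity, so the whitened noise
floor stays flat and the peak/median SNR statistic is unbiased.  Plain first
differencing is selectable with ``method="diff"``.

SNR is defined here (the source procedures leave it unspecified) as the
power at the detected peak divided by the median in-band power, excluding
bins within one resolution step of the peak and of its second harmonic.
On a single raw periodogram the maximum of ~40 exponentially-distributed
noise bins sits 3-5x above their median, so noise-floor medians for SNR
are taken from a Welch-averaged spectrum (:func:`welch_spectrum`) whose
bin variance is reduced by segment averaging; peak *localization* uses the
full-resolution periodogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import (
    InsufficientBinsError,
    InsufficientDataError,
    NyquistError,
    ValidationError,
)
from .framestore import PixelTrace

log = logging.getLogger(__name__)

#: maximum timestamp jitter tolerated (fraction of the frame interval) before
#: an epoch is rejected; below this the trace is linearly resampled.
JITTER_TOLERANCE = 0.05


@dataclass
class Band:
    """Frequency search band in events/min."""

    lo_bpm: float
    hi_bpm: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo_bpm < self.hi_bpm:
            raise ValidationError(f"invalid band [{self.lo_bpm}, {self.hi_bpm}]")


@dataclass
class Spectrum:
    """One-sided power spectrum with frequencies in events/min."""

    freq_bpm: np.ndarray
    power: np.ndarray
    window_s: float

    def __post_init__(self) -> None:
        self.freq_bpm = np.asarray(self.freq_bpm, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.freq_bpm.size == 0 or self.freq_bpm.size != self.power.size:
            raise ValidationError("spectrum frequencies/power mismatch")
        if np.any(np.diff(self.freq_bpm) <= 0) or self.freq_bpm[0] < 0:
            raise ValidationError("frequencies must be strictly increasing and >= 0")
        if np.any(self.power < 0):
            raise ValidationError("spectral power must be non-negative")

    @property
    def resolution_bpm(self) -> float:
        return float(self.freq_bpm[1] - self.freq_bpm[0])

    @property
    def nyquist_bpm(self) -> float:
        return float(self.freq_bpm[-1])

    def band_mask(self, band: Band) -> np.ndarray:
        return (self.freq_bpm >= band.lo_bpm) & (self.freq_bpm <= band.hi_bpm)


@dataclass
class SpectralPeak:
    """The located in-band maximum and its signal-to-noise ratio."""

    freq_bpm: float
    power: float
    snr: float


def preprocess(trace: PixelTrace, method: str = "ar1") -> PixelTrace:
    """Zero-mean, detrended, whitened copy of ``trace`` (length preserved).

    Constant input is returned as an all-zero trace with
    ``flagged_constant=True`` rather than raising.
    """
    x = np.asarray(trace.values, dtype=np.float64)
    if x.size < 8:
        raise InsufficientDataError("preprocess needs at least 8 samples")
    if not np.all(np.isfinite(x)):
        raise ValidationError("trace contains non-finite values")
    scale = max(float(np.max(np.abs(x))), 1.0)
    if np.ptp(x) == 0:
        log.warning("constant trace: returning all-zero preprocessed trace")
        return PixelTrace(
            np.zeros_like(x), trace.timestamps_us, trace.source_roi, flagged_constant=True
        )
    x = sps.detrend(x, type="linear")
    if np.ptp(x) < 1e-9 * scale:  # pure trend: residual is float round-off
        log.warning("trend-only trace: returning all-zero preprocessed trace")
        return PixelTrace(
            np.zeros_like(x), trace.timestamps_us, trace.source_roi, flagged_constant=True
        )
    if method == "diff":
        w = np.diff(x, prepend=x[0])
    elif method == "ar1":
        denom = float(np.dot(x, x))
        rho = float(np.dot(x[1:], x[:-1]) / denom) if denom > 0 else 0.0
        rho = float(np.clip(rho, -0.98, 0.98))
        w = np.empty_like(x)
        w[0] = 0.0
        w[1:] = x[1:] - rho * x[:-1]
    else:
        raise ValidationError(f"unknown whitening method {method!r}")
    sd = w.std()
    if sd > 0:
        w = w / sd
    return PixelTrace(w, trace.timestamps_us, trace.source_roi)


def _uniform_values(trace: PixelTrace, fps: float, jitter_tol: float) -> np.ndarray:
    """Values on a uniform grid at ``fps``; resamples small timestamp jitter."""
    ts = trace.timestamps_us
    if ts.size != trace.values.size or ts.size < 2:
        return np.asarray(trace.values, dtype=np.float64)
    step = 1e6 / fps
    ideal = ts[0] + np.arange(ts.size) * step
    dev = np.max(np.abs(ts - ideal))
    if dev == 0:
        return np.asarray(trace.values, dtype=np.float64)
    if dev > jitter_tol * step:
        raise ValidationError(
            f"timestamp jitter {dev:.0f} us exceeds {jitter_tol:.0%} of the "
            f"frame interval; epoch rejected"
        )
    log.info("resampling trace with %.0f us timestamp jitter onto uniform grid", dev)
    return np.interp(ideal, ts.astype(np.float64), trace.values)


def power_spectrum(
    trace: PixelTrace, fps: float, jitter_tol: float = JITTER_TOLERANCE
) -> Spectrum:
    """Hann-windowed one-sided periodogram; frequencies in events/min."""
    if len(trace) == 0:
        raise InsufficientDataError("empty trace")
    values = _uniform_values(trace, fps, jitter_tol)
    freq_hz, power = sps.periodogram(values, fs=fps, window="hann", detrend=False)
    return Spectrum(freq_hz * 60.0, power, window_s=values.size / fps)


def welch_spectrum(
    trace: PixelTrace,
    fps: float,
    seg_fraction: float = 0.25,
    jitter_tol: float = JITTER_TOLERANCE,
) -> Spectrum:
    """Welch-averaged spectrum (50% overlap); coarser bins, stable noise floor."""
    if len(trace) == 0:
        raise InsufficientDataError("empty trace")
    values = _uniform_values(trace, fps, jitter_tol)
    nperseg = max(int(values.size * seg_fraction), 16)
    nperseg = min(nperseg, values.size)
    freq_hz, power = sps.welch(
        values, fs=fps, window="hann", nperseg=nperseg, detrend=False
    )
    return Spectrum(freq_hz * 60.0, power, window_s=nperseg / fps)


def snr(spec: Spectrum, peak_freq: float, band: Band) -> float:
    """Peak power over the median in-band power.

    Bins within one resolution step of ``peak_freq`` and of its second
    harmonic are excluded from the noise floor.  Requires >= 8 in-band bins.
    """
    if not band.lo_bpm <= peak_freq <= band.hi_bpm:
        raise ValidationError("peak_freq must lie within the band")
    mask = spec.band_mask(band)
    n_bins = int(mask.sum())
    if n_bins < 8:
        raise InsufficientBinsError(
            f"band [{band.lo_bpm}, {band.hi_bpm}]/min spans only {n_bins} bins (< 8)"
        )
    res = spec.resolution_bpm
    peak_idx = int(np.argmin(np.abs(spec.freq_bpm - peak_freq)))
    peak_power = float(spec.power[peak_idx])
    exclude = (np.abs(spec.freq_bpm - peak_freq) <= res) | (
        np.abs(spec.freq_bpm - 2.0 * peak_freq) <= res
    )
    noise_bins = spec.power[mask & ~exclude]
    if noise_bins.size == 0:
        noise_bins = spec.power[mask]
    floor = float(np.median(noise_bins))
    if floor == 0.0:
        return float("inf") if peak_power > 0 else 0.0
    return peak_power / floor


def band_peak(spec: Spectrum, band: Band) -> SpectralPeak:
    """In-band frequency of maximum power (ties break toward lower frequency)."""
    if band.lo_bpm > spec.nyquist_bpm:
        raise NyquistError(
            f"band [{band.lo_bpm}, {band.hi_bpm}]/min lies above the spectrum's "
            f"Nyquist limit of {spec.nyquist_bpm:g}/min"
        )
    mask = spec.band_mask(band)
    if not mask.any():
        raise NyquistError(
            f"band [{band.lo_bpm}, {band.hi_bpm}]/min contains no spectral bins "
            f"(Nyquist limit {spec.nyquist_bpm:g}/min, resolution "
            f"{spec.resolution_bpm:g}/min)"
        )
    idx = np.flatnonzero(mask)
    best = idx[int(np.argmax(spec.power[idx]))]  # argmax -> first, i.e. lower freq
    freq = float(spec.freq_bpm[best])
    try:
        ratio = snr(spec, freq, band)
    except InsufficientBinsError:
        ratio = float("nan")
    return SpectralPeak(freq_bpm=freq, power=float(spec.power[best]), snr=ratio)


def rate_peak(
    trace: PixelTrace, fps: float, band: Band, method: str = "ar1"
) -> tuple[SpectralPeak, Spectrum, Spectrum]:
    """Full chain for one trace: preprocess, locate the in-band peak on the
    periodogram, score its SNR against the Welch-averaged noise floor.

    Returns (peak, periodogram, welch_spectrum); ``peak.snr`` is the
    Welch-floor value when the band spans enough Welch bins, otherwise the
    periodogram value.
    """
    pre = preprocess(trace, method=method)
    spec = power_spectrum(pre, fps)
    wspec = welch_spectrum(pre, fps)
    peak = band_peak(spec, band)
    try:
        peak.snr = snr(wspec, min(max(peak.freq_bpm, band.lo_bpm), band.hi_bpm), band)
    except InsufficientBinsError:
        pass  # keep the periodogram-based value
    return peak, spec, wspec


def export_spectrum_csv(spec: Spectrum, path) -> None:
    """Write a spectrum as two-column CSV (freq_bpm, power)."""
    np.savetxt(
        path,
        np.column_stack([spec.freq_bpm, spec.power]),
        delimiter=",",
        header="freq_bpm,power",
        comments="",
    )
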