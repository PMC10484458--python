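"""System-requirement arithmetic and the three-ROI spectral validation report.

The sampling-theorem calculators answer "what rate can this frame rate
resolve" and its inverse: a signal is representable only below half the
sampling rate, so 40 fps supports heart rates up to 1200 beats/min and
20 fps supports respiratory rates up to 600 breaths/min.  The resolution
calculators cover the cage-coverage arithmetic (sensor pixels across the
field) and the eye-distinguishability requirement (2 px per 2.5 mm eye axis
-> ~1 px/mm).

The spectral report reproduces the validation workflow on a 15 s still
epoch: three labeled ROIs — the inner ear (iPPG carrier), the animal's
outer edge (respiratory boundary motion) and an animal-free reference —
each analyzed for the three characteristic bands (the ~6/min room
oscillation, 100-250/min respiratory, 400-600/min cardiac), with per-band
peaks and SNRs, and a paired comparison across two recordings (e.g.
ambient lighting on/off).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CageVitalsError, ConfigurationError, InsufficientDataError
from .framestore import FrameSequence, ROI, mean_trace
from .respiration import detect_still_epochs
from .spectral import (
    Band,
    band_peak,
    power_spectrum,
    preprocess,
    snr,
    welch_spectrum,
)

#: the three characteristic bands seen in in-vivo spectra, events/min
REPORT_BANDS: dict[str, Band] = {
    "room": Band(2.0, 30.0),
    "respiratory": Band(100.0, 250.0),
    "cardiac": Band(400.0, 600.0),
}

REQUIRED_ROI_LABELS = ("ear", "edge", "reference")


def max_detectable_rate(fps: float) -> float:
    """Highest rate (events/min) resolvable at ``fps``: fps * 60 / 2."""
    if fps <= 0:
        raise ValueError("fps must be positive")
    return fps * 60.0 / 2.0


def required_fps(max_rate_bpm: float) -> float:
    """Minimum frame rate for a target rate (events/min): 2 * rate / 60."""
    if max_rate_bpm <= 0:
        raise ValueError("rate must be positive")
    return 2.0 * max_rate_bpm / 60.0


def spatial_resolution(sensor_px: float, field_mm: float) -> float:
    """Achieved sampling density (px/mm) of a sensor spanning a field."""
    if sensor_px <= 0 or field_mm <= 0:
        raise ValueError("sensor_px and field_mm must be positive")
    return sensor_px / field_mm


def min_resolution_for_feature(px_per_axis: float, feature_mm: float) -> int:
    """Smallest integer px/mm that puts ``px_per_axis`` pixels on a feature."""
    if px_per_axis <= 0 or feature_mm <= 0:
        raise ValueError("px_per_axis and feature_mm must be positive")
    return math.ceil(px_per_axis / feature_mm)


@dataclass
class Check:
    name: str
    formula: str
    computed: float
    required: float
    passed: bool


@dataclass
class RequirementReport:
    """Named pass/fail checks, each carrying its formula string."""

    checks: list[Check] = field(default_factory=list)

    def add(self, name: str, formula: str, computed: float, required: float,
            passed: bool) -> None:
        self.checks.append(Check(name, formula, computed, required, passed))

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def to_json(self) -> str:
        return json.dumps(
            {
                "checks": [vars(c) for c in self.checks],
                "all_passed": self.all_passed,
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = []
        for c in self.checks:
            status = "PASS" if c.passed else "FAIL"
            lines.append(
                f"[{status}] {c.name}: {c.computed:g} (required {c.required:g}; "
                f"{c.formula})"
            )
        return "\n".join(lines)


def frame_rate_report(fps: float, target_hr_bpm: float = 1000.0,
                      target_rr_bpm: float = 400.0) -> RequirementReport:
    """Check a frame rate against cardiac and respiratory targets."""
    report = RequirementReport()
    limit = max_detectable_rate(fps)
    report.add(
        "heart_rate_nyquist",
        "max_detectable_rate = fps * 60 / 2 >= target HR",
        limit, target_hr_bpm, limit >= target_hr_bpm,
    )
    report.add(
        "respiratory_rate_nyquist",
        "max_detectable_rate = fps * 60 / 2 >= target RR",
        limit, target_rr_bpm, limit >= target_rr_bpm,
    )
    return report


def resolution_report(sensor_px: float, field_mm: float,
                      eye_mm: float = 2.5, px_per_eye_axis: float = 2.0,
                      ) -> RequirementReport:
    """Check spatial sampling against the eye-distinguishability requirement."""
    report = RequirementReport()
    achieved = spatial_resolution(sensor_px, field_mm)
    needed = min_resolution_for_feature(px_per_eye_axis, eye_mm)
    report.add(
        "eye_resolution",
        "sensor_px / field_mm >= ceil(px_per_eye_axis / eye_mm)",
        achieved, needed, achieved >= needed,
    )
    return report


def thermal_range_report(camera_lo_c: float, camera_hi_c: float) -> RequirementReport:
    """Check a radiometric camera's range against the 20-60 degC contract."""
    report = RequirementReport()
    report.add(
        "thermal_range_low",
        "camera range must start at or below +20 degC",
        camera_lo_c, 20.0, camera_lo_c <= 20.0,
    )
    report.add(
        "thermal_range_high",
        "camera range must extend to at least +60 degC",
        camera_hi_c, 60.0, camera_hi_c >= 60.0,
    )
    return report


@dataclass
class BandResult:
    band: Band
    peak_bpm: float
    peak_power: float
    snr: float | None  # None when the Welch band spans too few bins


@dataclass
class RoiSpectrum:
    label: str
    roi: ROI
    overall_peak_bpm: float
    overall_snr: float
    bands: dict[str, BandResult]
    freq_bpm: np.ndarray
    power: np.ndarray


@dataclass
class SpectralReport:
    """Per-ROI spectra with band annotations for one still epoch."""

    window_s: float
    fps: float
    rois: dict[str, RoiSpectrum]

    def to_json(self) -> str:
        payload = {"window_s": self.window_s, "fps": self.fps, "rois": {}}
        for label, rs in self.rois.items():
            payload["rois"][label] = {
                "roi": vars(rs.roi),
                "overall_peak_bpm": rs.overall_peak_bpm,
                "overall_snr": rs.overall_snr,
                "bands": {
                    name: {
                        "lo_bpm": br.band.lo_bpm,
                        "hi_bpm": br.band.hi_bpm,
                        "peak_bpm": br.peak_bpm,
                        "snr": br.snr,
                    }
                    for name, br in rs.bands.items()
                },
            }
        return json.dumps(payload, indent=2)

    def to_text(self) -> str:
        lines = [f"Spectral report ({self.window_s:g} s window, {self.fps:g} fps)"]
        for label, rs in self.rois.items():
            lines.append(
                f"  [{label}] overall peak {rs.overall_peak_bpm:g}/min "
                f"(SNR {rs.overall_snr:.2f})"
            )
            for name, br in rs.bands.items():
                s = f"{br.snr:.2f}" if br.snr is not None else "n/a"
                lines.append(
                    f"    {name} band {br.band.lo_bpm:g}-{br.band.hi_bpm:g}: "
                    f"peak {br.peak_bpm:g}/min, SNR {s}"
                )
        return "\n".join(lines)


def roi_spectral_report(
    nir_seq: FrameSequence,
    rois: dict[str, ROI],
    window_s: float = 15.0,
    bands: dict[str, Band] | None = None,
    search_band: Band | None = None,
    still_threshold: float = 0.02,
) -> SpectralReport:
    """Three-ROI spectral investigation over the first still epoch.

    ``rois`` must provide the labels 'ear', 'edge' and 'reference'.  Each
    ROI's mean trace is preprocessed; band peaks are located on the
    full-resolution periodogram, SNRs are scored against the Welch-averaged
    noise floor.
    """
    missing = [k for k in REQUIRED_ROI_LABELS if k not in rois]
    if missing:
        raise ConfigurationError(f"missing labeled ROI(s): {', '.join(missing)}")
    bands = dict(bands or REPORT_BANDS)
    fps = nir_seq.nominal_fps
    nyquist = fps * 60.0 / 2.0
    search = search_band or Band(30.0, nyquist)

    windows = detect_still_epochs(nir_seq, min_len_s=window_s, threshold=still_threshold)
    if not windows:
        raise InsufficientDataError(
            f"no still epoch of >= {window_s:g} s found; spectral validation "
            "requires motionless animals"
        )
    w = windows[0]
    n_frames = int(round(window_s * fps))
    sub = nir_seq.window(w.start_idx, min(w.start_idx + n_frames, w.end_idx))

    out: dict[str, RoiSpectrum] = {}
    for label, roi in rois.items():
        pre = preprocess(mean_trace(sub, roi))
        spec = power_spectrum(pre, fps)
        wspec = welch_spectrum(pre, fps)
        overall = band_peak(spec, search)
        try:
            overall_snr = snr(wspec, overall.freq_bpm, search)
        except CageVitalsError:
            overall_snr = overall.snr
        band_results: dict[str, BandResult] = {}
        for name, band in bands.items():
            if band.lo_bpm >= nyquist:
                continue
            peak = band_peak(spec, Band(band.lo_bpm, min(band.hi_bpm, nyquist)))
            try:
                band_snr: float | None = snr(wspec, peak.freq_bpm, band)
            except CageVitalsError:
                band_snr = None
            band_results[name] = BandResult(band, peak.freq_bpm, peak.power, band_snr)
        out[label] = RoiSpectrum(
            label=label,
            roi=roi,
            overall_peak_bpm=overall.freq_bpm,
            overall_snr=float(overall_snr),
            bands=band_results,
            freq_bpm=spec.freq_bpm,
            power=spec.power,
        )
    return SpectralReport(window_s=window_s, fps=fps, rois=out)


def compare_reports(
    report_a: SpectralReport, report_b: SpectralReport
) -> dict[str, dict[str, float]]:
    """Per-ROI, per-band SNR ratio b/a between two reports (e.g. lighting
    on over lighting off); values < 1 mean condition b degraded the SNR."""
    out: dict[str, dict[str, float]] = {}
    for label in report_a.rois:
        if label not in report_b.rois:
            continue
        ratios: dict[str, float] = {}
        for name, br_a in report_a.rois[label].bands.items():
            br_b = report_b.rois[label].bands.get(name)
            if br_b is None or br_a.snr in (None, 0) or br_b.snr is None:
                continue
            ratios[name] = br_b.snr / br_a.snr
        ratios["overall"] = (
            report_b.rois[label].overall_snr / report_a.rois[label].overall_snr
            if report_a.rois[label].overall_snr
            else float("nan")
        )
        out[label] = ratios
    return out
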