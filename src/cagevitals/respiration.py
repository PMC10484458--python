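"""Motion-based respiratory-rate estimation.

The respiratory cycle expands and contracts the body outline; from a
top-down view the outer areas of the body oscillate at the breathing
frequency with sub-pixel amplitude.  The pipeline:

1. restrict analysis to still epochs (locomotion corrupts the spectra),
2. select high-gradient feature points inside the thorax/edge ROI,
3. track each feature's sub-pixel displacement against the epoch's first
   frame via windowed phase cross-correlation,
4. project each feature's 2-D displacement onto its principal motion axis,
   detrend and whiten,
5. average the per-feature power spectra and take the in-band maximum.

Averaging spectra (rather than displacements) keeps a minority of bad
tracks from cancelling the signal.  The default search band is
30-400 breaths/min: the ceiling is the physiological maximum for mice, the
floor excludes the slow (~6/min) room-wide oscillation seen in real
recordings.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import sobel

from .errors import InsufficientDataError, NoFeaturesError, NyquistError, ValidationError
from .framestore import FrameSequence, Modality, PixelTrace, ROI
from .spectral import (
    Band,
    Spectrum,
    SpectralPeak,
    band_peak,
    power_spectrum,
    preprocess,
    snr,
    welch_spectrum,
)

log = logging.getLogger(__name__)

DEFAULT_RR_BAND = Band(30.0, 400.0)
DEFAULT_SNR_THRESHOLD = 3.0
#: normalized RMS lagged frame-difference threshold below which a pair is
#: "still"; sits between the breathing/noise floor (~0.7% of dynamic range)
#: and slow locomotion (>2%)
DEFAULT_STILL_THRESHOLD = 0.012


class Quality(str, enum.Enum):
    OK = "OK"
    LOW_SNR = "LOW_SNR"
    MOTION_REJECTED = "MOTION_REJECTED"


@dataclass
class VitalEstimate:
    """A rate estimate with its search band, SNR, window and quality flag."""

    rate_bpm: float
    band: Band
    snr: float
    window_us: tuple[int, int]
    quality: Quality
    modality: Modality | None = None

    def __post_init__(self) -> None:
        if self.quality is Quality.OK and not (
            self.band.lo_bpm <= self.rate_bpm <= self.band.hi_bpm
        ):
            raise ValidationError("OK estimate must lie within its search band")


@dataclass
class StillWindow:
    """Maximal run of frames whose pairwise motion energy stays below threshold."""

    start_idx: int
    end_idx: int  # half-open
    start_us: int
    end_us: int

    @property
    def duration_s(self) -> float:
        return (self.end_us - self.start_us) * 1e-6


@dataclass
class MotionTrajectory:
    """Per-feature displacement series (px) relative to the first frame."""

    displacements_px: np.ndarray  # (n_frames, n_features, 2) as (drow, dcol)
    seeds_px: np.ndarray  # (n_features, 2) feature locations in the first frame
    timestamps_us: np.ndarray

    def __post_init__(self) -> None:
        self.displacements_px = np.asarray(self.displacements_px, dtype=np.float64)
        if self.displacements_px.ndim != 3 or self.displacements_px.shape[2] != 2:
            raise ValidationError("displacements must have shape (n_frames, n_features, 2)")
        if self.displacements_px.shape[0] != np.asarray(self.timestamps_us).size:
            raise ValidationError("displacement frames and timestamps differ in length")
        if not np.all(np.isfinite(self.displacements_px)):
            raise ValidationError("displacements must be finite")

    @property
    def n_features(self) -> int:
        return self.displacements_px.shape[1]


def motion_energy(
    seq: FrameSequence, smooth_sigma: float = 2.0, lag_s: float = 0.5
) -> np.ndarray:
    """Normalized RMS difference between (smoothed) frames ``lag_s`` apart.

    Smoothing suppresses the per-pixel sensor-noise floor so spatially
    coherent change dominates the metric.  The lag makes the metric blind to
    zero-mean sub-pixel breathing oscillation while locomotion, which
    accumulates displacement, produces a large lagged difference.  The
    result is normalized by the sequence's dynamic range; entry i compares
    frames i and i+lag (length n_frames - lag).
    """
    lag = max(1, int(round(lag_s * seq.nominal_fps)))
    lag = min(lag, len(seq) - 1)
    lo = min(float(f.pixels.min()) for f in seq.frames)
    hi = max(float(f.pixels.max()) for f in seq.frames)
    dyn = hi - lo
    if dyn == 0:
        return np.zeros(len(seq) - lag)
    smoothed = [
        ndimage.gaussian_filter(np.asarray(f.pixels, dtype=np.float32), smooth_sigma)
        for f in seq.frames
    ]
    energy = np.empty(len(seq) - lag)
    for i in range(len(seq) - lag):
        d = smoothed[i + lag] - smoothed[i]
        d = d - d.mean()  # frame-wide illumination changes are not motion
        energy[i] = np.sqrt(np.mean(d * d, dtype=np.float64))
    return energy / dyn


def detect_still_epochs(
    seq: FrameSequence,
    min_len_s: float = 5.0,
    threshold: float = DEFAULT_STILL_THRESHOLD,
    smooth_sigma: float = 2.0,
    lag_s: float = 0.5,
) -> list[StillWindow]:
    """Maximal windows with motion energy below ``threshold`` for >= min_len_s."""
    if len(seq) < 2:
        return []
    lag = max(1, min(int(round(lag_s * seq.nominal_fps)), len(seq) - 1))
    energy = motion_energy(seq, smooth_sigma, lag_s)
    still = energy < threshold
    ts = seq.timestamps_us
    windows: list[StillWindow] = []
    i = 0
    n_trans = still.size
    while i < n_trans:
        if not still[i]:
            i += 1
            continue
        j = i
        while j < n_trans and still[j]:
            j += 1
        # lagged pairs (i..j-1, +lag) all still => frames [i, j-1+lag] are still
        end = j - 1 + lag + 1
        w = StillWindow(i, end, int(ts[i]), int(ts[end - 1]))
        # duration counts whole frame intervals: n frames cover n/fps seconds
        if (end - i) / seq.nominal_fps >= min_len_s:
            windows.append(w)
        i = j
    return windows


def _select_features(
    frame_px: np.ndarray,
    roi: ROI,
    max_features: int,
    min_distance: int,
    patch: int,
) -> np.ndarray:
    """Highest-gradient points inside ``roi``, patch-safe, as (row, col)."""
    grad = sobel(ndimage.gaussian_filter(frame_px.astype(np.float64), 1.0))
    rs, cs = roi.slices
    grad_roi = grad[rs, cs]
    dyn = float(np.ptp(frame_px))
    thr = 0.01 * dyn if dyn > 0 else np.inf
    # greedy strongest-first selection with a minimum separation; a plain
    # local-maximum detector finds almost nothing on a smooth boundary ridge
    candidates = np.argwhere(grad_roi >= thr)
    if candidates.size == 0:
        raise NoFeaturesError(f"no trackable features inside ROI {roi!r}")
    order = np.argsort(grad_roi[candidates[:, 0], candidates[:, 1]])[::-1]
    candidates = candidates[order]
    chosen: list[np.ndarray] = []
    for cand in candidates:
        if len(chosen) >= max_features:
            break
        if all(np.abs(cand - c).max() >= min_distance for c in chosen):
            chosen.append(cand)
    peaks = np.asarray(chosen) + np.array([roi.row0, roi.col0])
    half = patch // 2
    h, w = frame_px.shape
    ok = (
        (peaks[:, 0] >= half)
        & (peaks[:, 0] < h - half)
        & (peaks[:, 1] >= half)
        & (peaks[:, 1] < w - half)
    )
    peaks = peaks[ok]
    if peaks.size == 0:
        raise NoFeaturesError(f"all candidate features too close to the frame border")
    return peaks


def _subpixel_shifts(ref_patch: np.ndarray, patches: np.ndarray) -> np.ndarray:
    """Translation of each patch relative to ``ref_patch`` via windowed FFT
    cross-correlation with 3-point parabolic sub-pixel interpolation.

    All frames of one feature are registered in a single batched FFT, which
    is what makes dense per-frame tracking tractable.  Returns (n, 2) shifts
    as (drow, dcol).
    """
    p = ref_patch.shape[0]
    win = np.outer(np.hanning(p), np.hanning(p))
    ref_w = (ref_patch - ref_patch.mean()) * win
    cur_w = (patches - patches.mean(axis=(1, 2), keepdims=True)) * win
    corr = np.fft.irfft2(
        np.fft.rfft2(cur_w) * np.conj(np.fft.rfft2(ref_w))[None], s=(p, p)
    )
    corr = np.fft.fftshift(corr, axes=(1, 2))
    n = corr.shape[0]
    flat = corr.reshape(n, -1)
    peak = np.argmax(flat, axis=1)
    pr, pc = np.unravel_index(peak, (p, p))
    # clamp so the 3-point neighbourhood exists
    pr = np.clip(pr, 1, p - 2)
    pc = np.clip(pc, 1, p - 2)
    idx = np.arange(n)

    def parabola(cm: np.ndarray, c0: np.ndarray, cp: np.ndarray) -> np.ndarray:
        denom = cm - 2 * c0 + cp
        with np.errstate(divide="ignore", invalid="ignore"):
            off = 0.5 * (cm - cp) / denom
        off[~np.isfinite(off)] = 0.0
        return np.clip(off, -1.0, 1.0)

    dr = parabola(corr[idx, pr - 1, pc], corr[idx, pr, pc], corr[idx, pr + 1, pc])
    dc = parabola(corr[idx, pr, pc - 1], corr[idx, pr, pc], corr[idx, pr, pc + 1])
    center = p // 2
    return np.column_stack([pr + dr - center, pc + dc - center])


def track_breathing_motion(
    seq: FrameSequence,
    roi: ROI,
    max_features: int = 20,
    patch: int = 16,
    min_distance: int = 4,
) -> MotionTrajectory:
    """Sub-pixel displacement of gradient features in ``roi`` across frames.

    Each feature is a ``patch`` x ``patch`` window registered against the
    first frame by windowed cross-correlation with parabolic sub-pixel
    refinement.
    """
    roi.check_within(seq.shape)
    frame0 = np.asarray(seq.frames[0].pixels, dtype=np.float64)
    seeds = _select_features(frame0, roi, max_features, min_distance, patch)
    half = patch // 2
    n = len(seq)
    # only the union bounding box of all patches is ever touched
    r0 = int(seeds[:, 0].min()) - half
    r1 = int(seeds[:, 0].max()) + half
    c0 = int(seeds[:, 1].min()) - half
    c1 = int(seeds[:, 1].max()) + half
    sub = np.stack(
        [np.asarray(f.pixels[r0:r1, c0:c1], dtype=np.float64) for f in seq.frames]
    )
    disp = np.zeros((n, seeds.shape[0], 2), dtype=np.float64)
    for k, (r, c) in enumerate(seeds):
        rr, cc = r - r0, c - c0
        patches = sub[:, rr - half : rr + half, cc - half : cc + half]
        disp[:, k, :] = _subpixel_shifts(patches[0], patches)
    disp -= disp[0]  # displacement relative to the first frame
    return MotionTrajectory(disp, seeds.astype(np.float64), seq.timestamps_us)


def _principal_axis_series(disp_k: np.ndarray) -> np.ndarray:
    """Project one feature's (n, 2) displacement onto its principal axis."""
    centered = disp_k - disp_k.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]  # largest eigenvalue last
    return centered @ axis


def estimate_from_trajectory(
    traj: MotionTrajectory,
    fps: float,
    band: Band,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    modality: Modality | None = None,
    whiten: str = "ar1",
) -> VitalEstimate:
    """Shared motion-spectrum estimator used for both RR and motion-based HR."""
    nyquist_bpm = fps * 60.0 / 2.0
    if band.hi_bpm > nyquist_bpm:
        raise NyquistError(
            f"band ceiling {band.hi_bpm:g}/min exceeds the Nyquist limit "
            f"{nyquist_bpm:g}/min of {fps:g} fps; requires >= "
            f"{2 * band.hi_bpm / 60.0:g} fps"
        )
    if traj.n_features == 0:
        raise InsufficientDataError("trajectory holds no features")
    specs: list[Spectrum] = []
    wspecs: list[Spectrum] = []
    for k in range(traj.n_features):
        series = _principal_axis_series(traj.displacements_px[:, k, :])
        pre = preprocess(
            PixelTrace(series, traj.timestamps_us), method=whiten
        )
        specs.append(power_spectrum(pre, fps))
        wspecs.append(welch_spectrum(pre, fps))
    avg = Spectrum(
        specs[0].freq_bpm,
        np.mean([s.power for s in specs], axis=0),
        specs[0].window_s,
    )
    avg_w = Spectrum(
        wspecs[0].freq_bpm,
        np.mean([s.power for s in wspecs], axis=0),
        wspecs[0].window_s,
    )
    peak: SpectralPeak = band_peak(avg, band)
    try:
        peak_snr = snr(avg_w, min(max(peak.freq_bpm, band.lo_bpm), band.hi_bpm), band)
    except Exception:
        peak_snr = peak.snr
    quality = Quality.OK if peak_snr >= snr_threshold else Quality.LOW_SNR
    ts = traj.timestamps_us
    return VitalEstimate(
        rate_bpm=peak.freq_bpm,
        band=band,
        snr=float(peak_snr),
        window_us=(int(ts[0]), int(ts[-1])),
        quality=quality,
        modality=modality,
    )


def estimate_rr(
    traj: MotionTrajectory,
    fps: float,
    band: Band = DEFAULT_RR_BAND,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
) -> VitalEstimate:
    """Respiratory rate from a still-epoch motion trajectory."""
    return estimate_from_trajectory(traj, fps, band, snr_threshold)


def analyze_sequence(
    seq: FrameSequence,
    roi: ROI,
    band: Band = DEFAULT_RR_BAND,
    min_len_s: float = 5.0,
    still_threshold: float = DEFAULT_STILL_THRESHOLD,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    max_features: int = 20,
) -> list[VitalEstimate]:
    """Per-epoch RR estimates; moving spans yield MOTION_REJECTED entries."""
    windows = detect_still_epochs(seq, min_len_s, still_threshold)
    estimates: list[VitalEstimate] = []
    covered = np.zeros(len(seq), dtype=bool)
    for w in windows:
        covered[w.start_idx : w.end_idx] = True
        sub = seq.window(w.start_idx, w.end_idx)
        try:
            traj = track_breathing_motion(sub, roi, max_features=max_features)
        except NoFeaturesError:
            log.warning("epoch [%d, %d): no trackable features", w.start_idx, w.end_idx)
            continue
        estimates.append(
            estimate_rr(traj, seq.nominal_fps, band, snr_threshold)
        )
    if not covered.all():
        ts = seq.timestamps_us
        estimates.append(
            VitalEstimate(
                rate_bpm=float("nan"),
                band=band,
                snr=0.0,
                window_us=(int(ts[0]), int(ts[-1])),
                quality=Quality.MOTION_REJECTED,
                modality=seq.modality,
            )
        )
    return estimates
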