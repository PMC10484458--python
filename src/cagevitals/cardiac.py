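"""Heart-rate estimation from NIR video.

Primary path: imaging photoplethysmography (iPPG) — blood-volume variation
modulates the brightness of fur-free skin (ears, face, tail) at the cardiac
frequency.  NIR illumination penetrates tissue, so the single NIR intensity
channel is the PPG carrier; no chrominance combination is attempted.  The
secondary path reuses the motion machinery of the respiration module on
ballistic micro-motion with a cardiac search band.

Default bands: mouse 200-1000 beats/min (maximum HR 800-1000), rat
150-600 beats/min.  At the nominal 40 fps the Nyquist ceiling is
1200 beats/min; estimation on lossy-compressed input is refused by default
because encoding destroys the weak PPG signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import NyquistError
from .framestore import Frame, FrameSequence, Modality, ROI, mean_trace, require_uncompressed
from .respiration import (
    DEFAULT_SNR_THRESHOLD,
    MotionTrajectory,
    Quality,
    VitalEstimate,
    estimate_from_trajectory,
)
from .spectral import Band, rate_peak

log = logging.getLogger(__name__)

MOUSE_HR_BAND = Band(200.0, 1000.0)
RAT_HR_BAND = Band(150.0, 600.0)
SPECIES_BANDS = {"mouse": MOUSE_HR_BAND, "rat": RAT_HR_BAND}


@dataclass
class SkinPatch:
    """A candidate fur-free patch: its bounding ROI and pixel area."""

    roi: ROI
    area_px: int


def detect_skin_rois(
    frame: Frame,
    min_area_px: int = 4,
    min_body_area_px: int = 50,
    brightness_fraction: float = 0.25,
    min_contrast_sigmas: float = 6.0,
) -> list[ROI]:
    """Candidate fur-free skin patches, ranked by area (largest first).

    The body is segmented from the floor by Otsu thresholding; within the
    body mask, compact regions whose intensity exceeds the body median by
    ``brightness_fraction`` of the median-to-maximum span are kept.  An
    empty list is returned when no animal is present (callers fall back to
    a manual ROI).
    """
    px = np.asarray(frame.pixels, dtype=np.float64)
    if np.ptp(px) == 0:
        return []
    thr = threshold_otsu(px)
    body = px > thr
    if body.sum() < min_body_area_px or (~body).sum() == 0:
        return []
    # reject a "body" that is just the upper tail of sensor noise
    fg, bg = px[body], px[~body]
    within_sd = max(float(np.sqrt((fg.var() + bg.var()) / 2.0)), 1e-12)
    if (fg.mean() - bg.mean()) < min_contrast_sigmas * within_sd:
        return []
    body_median = float(np.median(fg))
    body_max = float(fg.max())
    skin_thr = body_median + brightness_fraction * (body_max - body_median)
    skin = body & (px > skin_thr)
    labels, n = ndimage.label(skin)
    patches: list[SkinPatch] = []
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        region = labels[sl] > 0
        area = int(region.sum())
        if area < min_area_px:
            continue
        roi = ROI(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop, label="skin")
        patches.append(SkinPatch(roi, area))
    patches.sort(key=lambda p: p.area_px, reverse=True)
    return [p.roi for p in patches]


def estimate_hr_intensity(
    seq: FrameSequence,
    roi: ROI,
    band: Band = MOUSE_HR_BAND,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    allow_compressed: bool = False,
) -> VitalEstimate:
    """iPPG heart rate: ROI mean trace -> whiten -> spectrum -> in-band peak.

    The sequence must be a still epoch; locomotion must be rejected upstream
    (see :func:`cagevitals.respiration.detect_still_epochs`).
    """
    require_uncompressed(seq, allow_compressed)
    fps = seq.nominal_fps
    nyquist_bpm = fps * 60.0 / 2.0
    if band.hi_bpm > nyquist_bpm:
        raise NyquistError(
            f"band ceiling {band.hi_bpm:g}/min exceeds the Nyquist limit "
            f"{nyquist_bpm:g}/min of {fps:g} fps; requires >= "
            f"{2 * band.hi_bpm / 60.0:g} fps"
        )
    trace = mean_trace(seq, roi)
    peak, _, _ = rate_peak(trace, fps, band)
    quality = Quality.OK if peak.snr >= snr_threshold else Quality.LOW_SNR
    ts = seq.timestamps_us
    return VitalEstimate(
        rate_bpm=peak.freq_bpm,
        band=band,
        snr=float(peak.snr),
        window_us=(int(ts[0]), int(ts[-1])),
        quality=quality,
        modality=Modality.NIR,
    )


def estimate_hr_motion(
    traj: MotionTrajectory,
    fps: float,
    band: Band = MOUSE_HR_BAND,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
) -> VitalEstimate:
    """Motion-based heart rate from ballistic micro-motion trajectories."""
    return estimate_from_trajectory(traj, fps, band, snr_threshold)
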