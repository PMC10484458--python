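"""Position/velocity tracking, occupancy heat maps, circadian summaries.

Tracking works on the thermal modality, where the warm body against the
cooler floor makes segmentation trivial and robust.  Identity of individual
animals is not maintained (group-housed mice are visually identical); the
per-frame detection is the largest warm component, and occupancy aggregates
over whatever was detected.

The circadian periodogram is least-squares spectral analysis
(Lomb-Scargle), which tolerates the gaps that handling and occlusion leave
in real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import lombscargle

from .errors import InsufficientDataError, ValidationError
from .framestore import FrameSequence, Modality
from .thermometry import DEFAULT_SEGMENT_THRESHOLD_C, segment_animal


@dataclass
class Trajectory:
    """Per-frame centroid in cage coordinates (mm), with validity flags."""

    positions_mm: np.ndarray  # (n, 2) as (x, y); NaN where invalid
    valid: np.ndarray  # (n,) bool
    timestamps_us: np.ndarray

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.timestamps_us = np.asarray(self.timestamps_us, dtype=np.int64)
        n = self.timestamps_us.size
        if self.positions_mm.shape != (n, 2) or self.valid.shape != (n,):
            raise ValidationError("trajectory arrays must share the frame count")

    def __len__(self) -> int:
        return self.valid.size


@dataclass
class OccupancyMap:
    """Cumulative dwell time (s) per cage-floor cell.

    Dwell is stored as integer frame counts times the frame interval so the
    conservation identity total == n_valid_frames * frame_interval holds
    exactly, not merely to rounding.
    """

    counts: np.ndarray  # (rows, cols) valid-frame counts covering (depth, width)
    interval_s: float
    cell_mm: float
    cage_mm: tuple[float, float]

    @property
    def dwell_s(self) -> np.ndarray:
        return self.counts * self.interval_s

    @property
    def total_s(self) -> float:
        return float(int(self.counts.sum()) * self.interval_s)


@dataclass
class CircadianProfile:
    """Binned mean activity with the dominant period of the rhythm."""

    bin_start_h: np.ndarray
    mean_speed: np.ndarray  # mm/s per bin (NaN for empty bins)
    dominant_period_h: float
    power_ratio: float  # peak periodogram power over the median
    low_confidence: bool  # recording spans fewer than two full periods


def track_positions(
    seq: FrameSequence,
    threshold_c: float = DEFAULT_SEGMENT_THRESHOLD_C,
    min_area_px: int = 25,
) -> Trajectory:
    """Per-frame centroid of the largest warm component, in mm."""
    if seq.modality is not Modality.THERMAL:
        raise ValidationError("position tracking expects the thermal modality")
    if not seq.px_per_mm:
        raise ValidationError("px_per_mm must be known to convert positions to mm")
    ppm = float(seq.px_per_mm)
    n = len(seq)
    positions = np.full((n, 2), np.nan)
    valid = np.zeros(n, dtype=bool)
    for i, frame in enumerate(seq.frames):
        mask = segment_animal(frame, threshold_c, min_area_px)
        body = mask.largest_component()
        if not body.any():
            continue
        r, c = ndimage.center_of_mass(body)
        positions[i] = (c / ppm, r / ppm)  # (x, y) in mm
        valid[i] = True
    return Trajectory(positions, valid, seq.timestamps_us)


def speed(traj: Trajectory) -> np.ndarray:
    """Per-frame speed (mm/s) by centered finite differences.

    NaN wherever the frame or a needed neighbour is invalid; endpoints use
    one-sided differences.
    """
    n = len(traj)
    if n < 2:
        raise InsufficientDataError("speed needs at least 2 frames")
    v = traj.valid
    if not np.any(v[:-1] & v[1:]):
        raise InsufficientDataError("no pair of consecutive valid frames")
    t = traj.timestamps_us * 1e-6
    p = traj.positions_mm
    out = np.full(n, np.nan)
    # centered differences
    ok = v[2:] & v[:-2] & v[1:-1]
    idx = np.flatnonzero(ok) + 1
    if idx.size:
        d = p[idx + 1] - p[idx - 1]
        dt = t[idx + 1] - t[idx - 1]
        out[idx] = np.hypot(d[:, 0], d[:, 1]) / dt
    # one-sided ends
    if v[0] and v[1]:
        out[0] = np.hypot(*(p[1] - p[0])) / (t[1] - t[0])
    if v[-1] and v[-2]:
        out[-1] = np.hypot(*(p[-1] - p[-2])) / (t[-1] - t[-2])
    return out


def occupancy_map(
    traj: Trajectory, cell_mm: float, cage_mm: tuple[float, float]
) -> OccupancyMap:
    """Dwell-time grid: each valid frame adds one frame interval to the cell
    containing its centroid.  Total dwell time is conserved exactly:
    sum(map) == n_valid * frame_interval.
    """
    if cell_mm <= 0:
        raise ValidationError("cell_mm must be positive")
    n = len(traj)
    t = traj.timestamps_us
    interval_s = float((t[-1] - t[0]) * 1e-6 / (n - 1)) if n > 1 else 0.0
    n_cols = int(np.ceil(cage_mm[0] / cell_mm))
    n_rows = int(np.ceil(cage_mm[1] / cell_mm))
    counts = np.zeros((n_rows, n_cols), dtype=np.int64)
    p = traj.positions_mm[traj.valid]
    if p.size:
        cols = np.clip((p[:, 0] // cell_mm).astype(int), 0, n_cols - 1)
        rows = np.clip((p[:, 1] // cell_mm).astype(int), 0, n_rows - 1)
        np.add.at(counts, (rows, cols), 1)
    return OccupancyMap(counts, interval_s, cell_mm, tuple(cage_mm))


def circadian_profile(
    timestamps_s: np.ndarray,
    speeds: np.ndarray,
    bin_h: float = 1.0,
    max_period_h: float = 48.0,
) -> CircadianProfile:
    """Mean activity per time bin plus the dominant rhythm period.

    The periodogram is evaluated on the binned series over periods from
    2 x bin_h up to min(span, max_period_h).  The result is flagged
    low-confidence when the recording covers fewer than two full cycles of
    the dominant period (a single day cannot pin down a 24 h rhythm).
    """
    timestamps_s = np.asarray(timestamps_s, dtype=np.float64)
    speeds = np.asarray(speeds, dtype=np.float64)
    if timestamps_s.shape != speeds.shape:
        raise ValidationError("timestamps and speeds must have the same length")
    finite = np.isfinite(speeds)
    timestamps_s, speeds = timestamps_s[finite], speeds[finite]
    if timestamps_s.size < 2:
        raise InsufficientDataError("need at least two activity samples")
    span_h = (timestamps_s[-1] - timestamps_s[0]) / 3600.0
    if span_h < 2 * bin_h:
        raise InsufficientDataError(
            f"recording span {span_h:.2f} h is shorter than two {bin_h:g} h bins"
        )
    t_h = (timestamps_s - timestamps_s[0]) / 3600.0
    n_bins = int(np.ceil(span_h / bin_h))
    edges = np.arange(n_bins + 1) * bin_h
    which = np.clip(np.digitize(t_h, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=speeds, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_speed = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = edges[:-1] + bin_h / 2.0

    filled = np.isfinite(mean_speed)
    y = mean_speed[filled] - np.nanmean(mean_speed)
    x_h = centers[filled]
    if np.ptp(y) == 0:
        return CircadianProfile(edges[:-1], mean_speed, float("nan"), 0.0, True)
    periods = np.arange(2 * bin_h, min(span_h, max_period_h) + bin_h / 4, bin_h / 4)
    omega = 2 * np.pi / periods
    power = lombscargle(x_h, y, omega, normalize=True)
    best = int(np.argmax(power))
    dominant = float(periods[best])
    med = float(np.median(power))
    ratio = float(power[best] / med) if med > 0 else float("inf")
    low_confidence = span_h < 2 * dominant
    return CircadianProfile(edges[:-1], mean_speed, dominant, ratio, low_confidence)
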