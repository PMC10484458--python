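"""Surface and core-proxy temperature extraction from radiometric frames.

The animal is segmented from the cooler cage floor by a plain temperature
threshold (default 30 degC, between the ~22 degC room contract and body
temperature).  Surface temperature is the mean over the body mask; the core
proxy is the 95th-percentile temperature inside an eye ROI — the periorbital
region is the warmest externally visible surface and tracks core
temperature.  A reading is valid only when every contributing pixel lies
within the radiometric camera contract of +20 to +60 degC.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import NoAnimalError, ResolutionError, ValidationError
from .framestore import Frame, Modality, ROI

THERMAL_RANGE_C = (20.0, 60.0)
DEFAULT_SEGMENT_THRESHOLD_C = 30.0
DEFAULT_MIN_AREA_PX = 25
EYE_PERCENTILE = 95.0


class ReadingKind(str, enum.Enum):
    SURFACE_MEAN = "SURFACE_MEAN"
    EYE_CORE_PROXY = "EYE_CORE_PROXY"


@dataclass
class TemperatureReading:
    value_c: float
    kind: ReadingKind
    n_pixels: int
    valid: bool


@dataclass
class BodyMask:
    """Boolean per-pixel animal mask with the threshold that produced it."""

    mask: np.ndarray
    threshold_c: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_components(self) -> int:
        _, n = ndimage.label(self.mask)
        return int(n)

    def largest_component(self) -> np.ndarray:
        labels, n = ndimage.label(self.mask)
        if n == 0:
            return np.zeros_like(self.mask)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        return labels == (int(np.argmax(sizes)) + 1)


def _require_thermal(frame: Frame) -> np.ndarray:
    if frame.modality is not Modality.THERMAL:
        raise ValidationError("thermometry requires a THERMAL frame")
    return np.asarray(frame.pixels, dtype=np.float64)


def _range_valid(values: np.ndarray) -> bool:
    lo, hi = THERMAL_RANGE_C
    return bool(np.all((values >= lo) & (values <= hi)))


def segment_animal(
    frame: Frame,
    threshold_c: float = DEFAULT_SEGMENT_THRESHOLD_C,
    min_area_px: int = DEFAULT_MIN_AREA_PX,
) -> BodyMask:
    """Connected warm regions (> threshold), small components removed."""
    px = _require_thermal(frame)
    raw = px > threshold_c
    labels, n = ndimage.label(raw)
    mask = np.zeros_like(raw)
    for i in range(1, n + 1):
        component = labels == i
        if component.sum() >= min_area_px:
            mask |= component
    return BodyMask(mask, threshold_c)


def surface_temperature(frame: Frame, mask: BodyMask) -> TemperatureReading:
    """Mean skin temperature over the body mask."""
    px = _require_thermal(frame)
    if mask.mask.shape != px.shape:
        raise ValidationError("mask shape does not match frame shape")
    values = px[mask.mask]
    if values.size == 0:
        raise NoAnimalError("empty body mask: no animal to measure")
    value = float(values.mean())
    lo, hi = THERMAL_RANGE_C
    valid = _range_valid(values) and lo <= value <= hi
    return TemperatureReading(value, ReadingKind.SURFACE_MEAN, int(values.size), valid)


def eye_core_proxy(frame: Frame, eye_roi: ROI) -> TemperatureReading:
    """Core-temperature proxy: 95th-percentile temperature inside the eye ROI.

    The percentile (rather than the maximum) is robust to single-pixel
    noise.  Requires the eye to be resolved by at least 2 x 2 px, i.e.
    ~1 px/mm for a 2.5 mm mouse eye.
    """
    px = _require_thermal(frame)
    if eye_roi.height < 2 or eye_roi.width < 2:
        raise ResolutionError(
            f"eye ROI {eye_roi.height}x{eye_roi.width} px is below the 2x2 px "
            "minimum: ~1 px/mm spatial sampling is needed to resolve a mouse eye"
        )
    eye_roi.check_within(px.shape)
    rs, cs = eye_roi.slices
    values = px[rs, cs].ravel()
    value = float(np.percentile(values, EYE_PERCENTILE))
    lo, hi = THERMAL_RANGE_C
    valid = _range_valid(values) and lo <= value <= hi
    return TemperatureReading(value, ReadingKind.EYE_CORE_PROXY, int(values.size), valid)
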