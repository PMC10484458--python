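"""Timestamped frame sequences, ROIs and scalar pixel traces.

The on-disk container is a directory holding a multipage lossless TIFF
(``frames.tif``) plus a JSON sidecar (``meta.json``) with modality, nominal
frame rate, spatial sampling density, bit depth and the per-frame timestamps
in integer microseconds.  NIR intensity frames are stored as float32;
radiometric thermal frames are stored as unsigned 16-bit centi-kelvin and
converted to degrees Celsius on load.  Both directions are lossless, so a
save -> load round trip is bit-exact.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .errors import (
    BoundsError,
    CompressedInputError,
    FormatError,
    InsufficientDataError,
    ValidationError,
)

log = logging.getLogger(__name__)

_KELVIN_OFFSET_C = 273.15

SIDECAR_NAME = "meta.json"
STACK_NAME = "frames.tif"


class Modality(str, enum.Enum):
    NIR = "NIR"
    THERMAL = "THERMAL"


def _centikelvin_to_celsius(ck: np.ndarray) -> np.ndarray:
    return ck.astype(np.float64) / 100.0 - _KELVIN_OFFSET_C


def _celsius_to_centikelvin(c: np.ndarray) -> np.ndarray:
    ck = np.round((np.asarray(c, dtype=np.float64) + _KELVIN_OFFSET_C) * 100.0)
    if ck.min() < 0 or ck.max() > np.iinfo(np.uint16).max:
        raise ValidationError("thermal values outside the uint16 centi-kelvin range")
    return ck.astype(np.uint16)


@dataclass
class Frame:
    """A single 2-D image: NIR intensity (dimensionless) or temperature (degC)."""

    pixels: np.ndarray
    timestamp_us: int
    modality: Modality

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("frame pixels must be a non-empty 2-D array")
        self.timestamp_us = int(self.timestamp_us)
        self.modality = Modality(self.modality)
        if self.modality is Modality.THERMAL:
            if not np.all(np.isfinite(self.pixels)):
                raise ValidationError("thermal pixels must be finite")
        else:
            if not np.all(self.pixels >= 0):
                raise ValidationError("NIR pixels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ROI:
    """Axis-aligned rectangle, 0-based, half-open: [row0,row1) x [col0,col1)."""

    row0: int
    col0: int
    row1: int
    col1: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValidationError(f"degenerate ROI {self!r}")
        if self.row0 < 0 or self.col0 < 0:
            raise ValidationError(f"negative ROI origin {self!r}")

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)

    def check_within(self, shape: tuple[int, int]) -> None:
        if self.row1 > shape[0] or self.col1 > shape[1]:
            raise BoundsError(f"ROI {self!r} exceeds frame shape {shape}")

    def iou(self, other: "ROI") -> float:
        """Intersection-over-union with another ROI."""
        r0 = max(self.row0, other.row0)
        c0 = max(self.col0, other.col0)
        r1 = min(self.row1, other.row1)
        c1 = min(self.col1, other.col1)
        inter = max(0, r1 - r0) * max(0, c1 - c0)
        union = self.height * self.width + other.height * other.width - inter
        return inter / union if union else 0.0


@dataclass
class PixelTrace:
    """Scalar-per-frame signal, e.g. the spatial mean over an ROI."""

    values: np.ndarray
    timestamps_us: np.ndarray
    source_roi: ROI | None = None
    flagged_constant: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.timestamps_us = np.asarray(self.timestamps_us, dtype=np.int64)
        if self.values.shape != self.timestamps_us.shape:
            raise ValidationError("trace values and timestamps differ in length")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class FrameSequence:
    """Ordered frames of one modality with strictly increasing timestamps."""

    frames: list[Frame]
    nominal_fps: float
    px_per_mm: float | None = None
    compressed: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValidationError("FrameSequence requires at least one frame")
        shape = self.frames[0].shape
        modality = self.frames[0].modality
        for f in self.frames:
            if f.shape != shape or f.modality is not modality:
                raise ValidationError("all frames must share shape and modality")
        ts = self.timestamps_us
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def modality(self) -> Modality:
        return self.frames[0].modality

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def timestamps_us(self) -> np.ndarray:
        return np.asarray([f.timestamp_us for f in self.frames], dtype=np.int64)

    def pixel_array(self) -> np.ndarray:
        """All frames stacked into a (n_frames, H, W) array."""
        return np.stack([f.pixels for f in self.frames])

    def crop(self, roi: ROI) -> "FrameSequence":
        roi.check_within(self.shape)
        rs, cs = roi.slices
        frames = [
            Frame(f.pixels[rs, cs], f.timestamp_us, f.modality) for f in self.frames
        ]
        return FrameSequence(
            frames, self.nominal_fps, self.px_per_mm, self.compressed, dict(self.metadata)
        )

    def window(self, start_idx: int, end_idx: int) -> "FrameSequence":
        """Sub-sequence of frames [start_idx, end_idx)."""
        return FrameSequence(
            self.frames[start_idx:end_idx],
            self.nominal_fps,
            self.px_per_mm,
            self.compressed,
            dict(self.metadata),
        )

    @classmethod
    def from_array(
        cls,
        pixels: np.ndarray,
        timestamps_us: Sequence[int],
        modality: Modality,
        nominal_fps: float,
        px_per_mm: float | None = None,
        compressed: bool = False,
    ) -> "FrameSequence":
        frames = [
            Frame(p, t, modality) for p, t in zip(pixels, timestamps_us, strict=True)
        ]
        return cls(frames, nominal_fps, px_per_mm, compressed)


def effective_fps(seq: FrameSequence) -> float:
    """Realized frame rate (n-1) / (t_last - t_first), in frames/s."""
    if len(seq) < 2:
        raise InsufficientDataError("effective_fps needs at least 2 frames")
    ts = seq.timestamps_us
    return (len(seq) - 1) / ((ts[-1] - ts[0]) * 1e-6)


def mean_trace(seq: FrameSequence, roi: ROI) -> PixelTrace:
    """Spatial mean over ``roi`` for every frame."""
    roi.check_within(seq.shape)
    rs, cs = roi.slices
    values = np.asarray(
        [float(f.pixels[rs, cs].mean()) for f in seq.frames], dtype=np.float64
    )
    return PixelTrace(values, seq.timestamps_us, source_roi=roi)


def save_sequence(seq: FrameSequence, path: str | Path) -> Path:
    """Write a sequence as a TIFF stack + JSON sidecar into directory ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    stack = seq.pixel_array()
    if seq.modality is Modality.THERMAL:
        data = _celsius_to_centikelvin(stack)
        bit_depth = 16
    else:
        data = stack.astype(np.float32)
        bit_depth = 32
    tifffile.imwrite(path / STACK_NAME, data, compression=None)
    sidecar = {
        "modality": seq.modality.value,
        "nominal_fps": seq.nominal_fps,
        "px_per_mm": seq.px_per_mm,
        "bit_depth": bit_depth,
        "compressed": seq.compressed,
        "timestamps_us": [int(t) for t in seq.timestamps_us],
        "metadata": seq.metadata,
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar))
    return path


def load_sequence(path: str | Path) -> FrameSequence:
    """Load a sequence saved by :func:`save_sequence` (bit-exact round trip)."""
    path = Path(path)
    sidecar_path = path / SIDECAR_NAME
    stack_path = path / STACK_NAME
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    if not stack_path.exists():
        raise FormatError(f"missing frame stack {stack_path}")
    sidecar = json.loads(sidecar_path.read_text())
    try:
        modality = Modality(sidecar["modality"])
        timestamps = np.asarray(sidecar["timestamps_us"], dtype=np.int64)
        nominal_fps = float(sidecar["nominal_fps"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"malformed sidecar {sidecar_path}: {exc}") from exc
    if timestamps.size > 1 and not np.all(np.diff(timestamps) > 0):
        raise ValidationError("sidecar timestamps are not strictly increasing")
    data = tifffile.imread(stack_path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != timestamps.size:
        raise FormatError(
            f"{stack_path}: {data.shape[0]} frames but {timestamps.size} timestamps"
        )
    if modality is Modality.THERMAL:
        data = _centikelvin_to_celsius(data)
    seq = FrameSequence.from_array(
        data,
        timestamps,
        modality,
        nominal_fps,
        px_per_mm=sidecar.get("px_per_mm"),
        compressed=bool(sidecar.get("compressed", False)),
    )
    seq.metadata = sidecar.get("metadata", {})
    return seq


def import_video(path: str | Path, modality: Modality, nominal_fps: float) -> FrameSequence:
    """Import a standard (lossy-compressed) video file as a FrameSequence.

    The result is marked ``compressed=True``: heart-rate estimation refuses
    such input by default because lossy encoding degrades the weak
    photoplethysmographic signal, while respiration/activity pipelines accept
    it with a logged warning.  Requires an imageio plugin able to decode the
    file.
    """
    try:
        import imageio.v3 as iio

        frames_px = iio.imread(path)
    except Exception as exc:  # pragma: no cover - depends on codec availability
        raise FormatError(f"cannot decode video {path}: {exc}") from exc
    if frames_px.ndim == 4:  # multi-channel: take the first channel (NIR carrier)
        frames_px = frames_px[..., 0]
    log.warning("imported compressed video %s; HR estimation will refuse it", path)
    step = 1e6 / nominal_fps
    timestamps = np.round(np.arange(frames_px.shape[0]) * step).astype(np.int64)
    return FrameSequence.from_array(
        frames_px.astype(np.float32), timestamps, modality, nominal_fps, compressed=True
    )


def require_uncompressed(seq: FrameSequence, allow_compressed: bool = False) -> None:
    """Refuse lossy-compressed input for SNR-critical pipelines."""
    if seq.compressed and not allow_compressed:
        raise CompressedInputError(
            "input is lossy-compressed: video encoding degrades the "
            "photoplethysmographic SNR; pass allow_compressed=True to override"
        )
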