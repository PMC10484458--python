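"""Synthetic home-cage recordings with known ground truth.

The generator emulates a top-down view of a EUROSTANDARD-style cage floor
(default 612 x 435 mm at 0.5 px/mm) containing one or more mouse-shaped
bodies rendered as anti-aliased ellipses:

* the body boundary dilates sinusoidally at the configured respiratory rate
  (breathing expansion/contraction, sub-pixel amplitudes expressible),
* a small fur-free "ear" patch has its intensity modulated sinusoidally at
  the configured heart rate (the photoplethysmographic carrier),
* the thermal modality renders the body at body temperature with a smooth
  edge gradient and the eye patch as the hottest region,
* additive Gaussian sensor noise per pixel, an optional frame-wide
  "ambient lighting" broadband noise term that raises the spectral noise
  floor, and an optional slow room-wide oscillation at 6 cycles/min.

All randomness is derived from ``SceneConfig.seed``; identical configs yield
bit-identical sequences.  NIR and thermal renders of the same config share
timestamps and geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import AliasingError, ValidationError
from .framestore import Frame, FrameSequence, Modality, ROI, save_sequence

# NIR appearance (arbitrary 8-bit-like intensity units)
NIR_FLOOR = 20.0
NIR_BODY = 100.0
NIR_EAR = 180.0

ROOM_OSCILLATION_BPM = 6.0  # slow building/illumination sway seen room-wide


@dataclass
class AnimalConfig:
    """One rodent: geometry, vital rates, modulation amplitudes, temperatures.

    Defaults describe an adult mouse: ~70 mm body, resting heart rate
    500 beats/min and respiratory rate 150 breaths/min (the ranges in which
    in-vivo spectra show their cardiac and respiratory harmonics), surface
    37 degC with the eye region ~1.5 degC warmer.  The relative PPG
    amplitude is synthetic, not a measured physiological value.
    """

    body_axes_mm: tuple[float, float] = (35.0, 15.0)  # semi-axes, major x minor
    ear_offset_mm: tuple[float, float] = (10.0, 3.0)  # from body center, (major, minor)
    ear_radius_mm: float = 4.0
    eye_offset_mm: tuple[float, float] = (14.0, 2.0)
    eye_radius_mm: float = 1.5
    hr_bpm: float = 500.0
    rr_bpm: float = 150.0
    ppg_amplitude: float = 0.05  # relative intensity modulation of the ear patch
    breath_amplitude_px: float = 0.8  # peak boundary displacement
    cardiac_motion_px: float = 0.0  # ballistic micro-motion of the boundary
    body_temp_c: float = 37.0
    eye_temp_c: float = 38.5
    angle_deg: float = 0.0  # body major-axis orientation
    breath_phase: float = 0.0
    ppg_phase: float = 0.0
    trajectory: list[tuple[float, float, float]] | None = None  # (t_s, x_mm, y_mm)

    def __post_init__(self) -> None:
        if not (self.hr_bpm > self.rr_bpm > 0):
            raise ValidationError("require hr_bpm > rr_bpm > 0")
        if min(self.ppg_amplitude, self.breath_amplitude_px, self.cardiac_motion_px) < 0:
            raise ValidationError("modulation amplitudes must be >= 0")
        for t in (self.body_temp_c, self.eye_temp_c):
            if not 20.0 <= t <= 60.0:
                raise ValidationError("temperatures must lie within 20-60 degC")


@dataclass
class SceneConfig:
    """Full parameterization of one synthetic recording."""

    cage_mm: tuple[float, float] = (612.0, 435.0)  # floor width x depth
    px_per_mm: float = 0.5
    fps: float = 40.0
    duration_s: float = 15.0
    animals: list[AnimalConfig] = field(default_factory=lambda: [AnimalConfig()])
    background_temp_c: float = 22.0
    sensor_noise_sd: float = 1.5  # NIR intensity units
    thermal_noise_sd_c: float = 0.05  # radiometric NETD-like noise, degC
    ambient_lighting: bool = False
    ambient_amplitude: float = 3.0  # frame-wide broadband term, NIR units
    room_oscillation: bool = False
    room_oscillation_amplitude: float = 2.0
    timestamp_jitter_us: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0 or self.px_per_mm <= 0:
            raise ValidationError("fps, duration_s and px_per_mm must be positive")
        if self.timestamp_jitter_us >= 0.5e6 / self.fps:
            raise ValidationError("timestamp jitter must stay below half a frame interval")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (
            int(round(self.cage_mm[1] * self.px_per_mm)),
            int(round(self.cage_mm[0] * self.px_per_mm)),
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneConfig":
        raw = json.loads(text)
        animal_raw = raw.pop("animals", None)
        if "cage_mm" in raw:
            raw["cage_mm"] = tuple(raw["cage_mm"])
        if animal_raw is not None:
            animals = []
            for a in animal_raw:
                for key in ("body_axes_mm", "ear_offset_mm", "eye_offset_mm"):
                    if key in a:
                        a[key] = tuple(a[key])
                if a.get("trajectory"):
                    a["trajectory"] = [tuple(w) for w in a["trajectory"]]
                animals.append(AnimalConfig(**a))
            raw["animals"] = animals
        return cls(**raw)


@dataclass
class GroundTruth:
    """True rates, temperatures and per-frame positions encoded by a scene."""

    timestamps_us: np.ndarray
    hr_bpm: list[float]
    rr_bpm: list[float]
    body_temp_c: list[float]
    eye_temp_c: list[float]
    positions_mm: np.ndarray  # (n_animals, n_frames, 2) as (x, y)

    def to_json(self) -> str:
        return json.dumps(
            {
                "timestamps_us": [int(t) for t in self.timestamps_us],
                "hr_bpm": self.hr_bpm,
                "rr_bpm": self.rr_bpm,
                "body_temp_c": self.body_temp_c,
                "eye_temp_c": self.eye_temp_c,
                "positions_mm": self.positions_mm.tolist(),
            }
        )


def _streams(config: SceneConfig) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(config.seed)
    ts, nir, thermal, ambient = root.spawn(4)
    return {
        "timestamps": np.random.default_rng(ts),
        "nir": np.random.default_rng(nir),
        "thermal": np.random.default_rng(thermal),
        "ambient": np.random.default_rng(ambient),
    }


def frame_timestamps(config: SceneConfig) -> np.ndarray:
    """Per-frame timestamps in integer microseconds (shared across modalities)."""
    n = config.n_frames
    step = 1e6 / config.fps
    ideal = np.round(np.arange(n) * step).astype(np.int64)
    if config.timestamp_jitter_us > 0:
        rng = _streams(config)["timestamps"]
        j = int(config.timestamp_jitter_us)
        ideal = ideal + rng.integers(-j, j + 1, size=n)
        ideal[0] = max(ideal[0], 0)
    return ideal


def _positions_mm(animal: AnimalConfig, config: SceneConfig, t_s: np.ndarray) -> np.ndarray:
    """Centroid (x, y) in mm at each frame time; linear waypoint interpolation."""
    if not animal.trajectory:
        center = (config.cage_mm[0] / 2.0, config.cage_mm[1] / 2.0)
        return np.tile(center, (t_s.size, 1))
    wp = np.asarray(animal.trajectory, dtype=np.float64)
    order = np.argsort(wp[:, 0])
    wp = wp[order]
    x = np.interp(t_s, wp[:, 0], wp[:, 1])
    y = np.interp(t_s, wp[:, 0], wp[:, 2])
    return np.column_stack([x, y])


def ground_truth(config: SceneConfig) -> GroundTruth:
    ts = frame_timestamps(config)
    t_s = ts * 1e-6
    if config.animals:
        positions = np.stack([_positions_mm(a, config, t_s) for a in config.animals])
    else:
        positions = np.zeros((0, ts.size, 2))
    return GroundTruth(
        timestamps_us=ts,
        hr_bpm=[a.hr_bpm for a in config.animals],
        rr_bpm=[a.rr_bpm for a in config.animals],
        body_temp_c=[a.body_temp_c for a in config.animals],
        eye_temp_c=[a.eye_temp_c for a in config.animals],
        positions_mm=positions,
    )


def _check_alias(config: SceneConfig, modality: Modality, allow_alias: bool) -> None:
    """Refuse to render rates above Nyquist for the given modality."""
    if allow_alias:
        return
    nyquist_bpm = config.fps * 60.0 / 2.0
    for a in config.animals:
        rendered = [a.rr_bpm] if a.breath_amplitude_px > 0 else []
        hr_rendered = a.cardiac_motion_px > 0 or (
            modality is Modality.NIR and a.ppg_amplitude > 0
        )
        if hr_rendered:
            rendered.append(a.hr_bpm)
        for rate in rendered:
            if rate > nyquist_bpm:
                raise AliasingError(
                    f"rate {rate:g}/min exceeds the Nyquist limit {nyquist_bpm:g}/min "
                    f"of {config.fps:g} fps; pass allow_alias=True to render anyway"
                )


def _ellipse_alpha(
    shape: tuple[int, int],
    center_rc: tuple[float, float],
    semi_rc: tuple[float, float],
    angle_deg: float,
) -> tuple[np.ndarray, tuple[slice, slice]]:
    """Anti-aliased coverage of an ellipse, computed on its bounding box only.

    The soft edge is ~1 px wide so sub-pixel boundary motion changes pixel
    values continuously.
    """
    cr, cc = center_rc
    sr, sc = semi_rc
    pad = max(sr, sc) + 2.0
    r0 = max(int(np.floor(cr - pad)), 0)
    r1 = min(int(np.ceil(cr + pad)) + 1, shape[0])
    c0 = max(int(np.floor(cc - pad)), 0)
    c1 = min(int(np.ceil(cc + pad)) + 1, shape[1])
    if r0 >= r1 or c0 >= c1:
        return np.zeros((0, 0)), (slice(0, 0), slice(0, 0))
    rows = np.arange(r0, r1, dtype=np.float64)[:, None] - cr
    cols = np.arange(c0, c1, dtype=np.float64)[None, :] - cc
    if angle_deg:
        th = np.deg2rad(angle_deg)
        u = rows * np.cos(th) - cols * np.sin(th)
        v = rows * np.sin(th) + cols * np.cos(th)
    else:
        u, v = rows, cols
    r = np.sqrt((u / sr) ** 2 + (v / sc) ** 2)
    # signed distance to the boundary, approximated radially
    alpha = np.clip((1.0 - r) * min(sr, sc) + 0.5, 0.0, 1.0)
    return alpha, (slice(r0, r1), slice(c0, c1))


def _render(config: SceneConfig, modality: Modality, allow_alias: bool) -> FrameSequence:
    _check_alias(config, modality, allow_alias)
    streams = _streams(config)
    ts = frame_timestamps(config)
    t_s = ts * 1e-6
    shape = config.frame_shape
    ppm = config.px_per_mm
    gt = ground_truth(config)
    is_nir = modality is Modality.NIR

    noise_rng = streams["nir" if is_nir else "thermal"]
    noise_sd = config.sensor_noise_sd if is_nir else config.thermal_noise_sd_c
    ambient_rng = streams["ambient"]
    ambient = (
        ambient_rng.normal(0.0, config.ambient_amplitude, size=config.n_frames)
        if (config.ambient_lighting and is_nir)
        else np.zeros(config.n_frames)
    )

    dtype = np.float32 if is_nir else np.float64
    frames: list[Frame] = []
    for i, t in enumerate(t_s):
        img = np.full(shape, NIR_FLOOR if is_nir else config.background_temp_c, dtype=dtype)
        for k, animal in enumerate(config.animals):
            x_mm, y_mm = gt.positions_mm[k, i]
            cr, cc = y_mm * ppm, x_mm * ppm
            dilation = animal.breath_amplitude_px * np.sin(
                2 * np.pi * animal.rr_bpm / 60.0 * t + animal.breath_phase
            ) + animal.cardiac_motion_px * np.sin(2 * np.pi * animal.hr_bpm / 60.0 * t)
            semi_r = animal.body_axes_mm[1] * ppm + dilation
            semi_c = animal.body_axes_mm[0] * ppm + dilation
            body_val = NIR_BODY if is_nir else animal.body_temp_c
            alpha, sl = _ellipse_alpha(shape, (cr, cc), (semi_r, semi_c), animal.angle_deg)
            img[sl] = img[sl] * (1 - alpha) + alpha * body_val

            if is_nir and animal.ear_radius_mm > 0:
                er = cr + animal.ear_offset_mm[1] * ppm
                ec = cc + animal.ear_offset_mm[0] * ppm
                ear_val = NIR_EAR * (
                    1.0
                    + animal.ppg_amplitude
                    * np.sin(2 * np.pi * animal.hr_bpm / 60.0 * t + animal.ppg_phase)
                )
                rad = animal.ear_radius_mm * ppm
                a2, sl2 = _ellipse_alpha(shape, (er, ec), (rad, rad), 0.0)
                img[sl2] = img[sl2] * (1 - a2) + a2 * ear_val
            if (not is_nir) and animal.eye_radius_mm > 0:
                er = cr + animal.eye_offset_mm[1] * ppm
                ec = cc + animal.eye_offset_mm[0] * ppm
                rad = max(animal.eye_radius_mm * ppm, 1.0)
                a2, sl2 = _ellipse_alpha(shape, (er, ec), (rad, rad), 0.0)
                img[sl2] = img[sl2] * (1 - a2) + a2 * animal.eye_temp_c

        if is_nir and config.room_oscillation:
            img += config.room_oscillation_amplitude * np.sin(
                2 * np.pi * ROOM_OSCILLATION_BPM / 60.0 * t
            )
        if is_nir:
            img += ambient[i]
        if noise_sd > 0:
            img += noise_rng.standard_normal(shape, dtype=np.float32) * noise_sd
        if is_nir:
            np.clip(img, 0.0, None, out=img)
        else:
            # radiometric sensor model: centi-kelvin quantization
            ck = np.round((img + 273.15) * 100.0)
            img = ck / 100.0 - 273.15
        frames.append(Frame(img, int(ts[i]), modality))
    return FrameSequence(frames, nominal_fps=config.fps, px_per_mm=ppm)


def render_nir(config: SceneConfig, allow_alias: bool = False) -> FrameSequence:
    """Render the NIR intensity modality (bright body on dark floor)."""
    return _render(config, Modality.NIR, allow_alias)


def render_thermal(config: SceneConfig, allow_alias: bool = False) -> FrameSequence:
    """Render the radiometric thermal modality (temperature-valued pixels)."""
    return _render(config, Modality.THERMAL, allow_alias)


# --------------------------------------------------------------------------
# Geometry helpers: ROIs derived from the scene ground truth, for the
# validation workflow and tests.

def _center_px(config: SceneConfig, animal_idx: int = 0) -> tuple[float, float]:
    gt = ground_truth(config)
    x_mm, y_mm = gt.positions_mm[animal_idx, 0]
    return y_mm * config.px_per_mm, x_mm * config.px_per_mm


def ear_roi(config: SceneConfig, animal_idx: int = 0, margin_px: int = 1) -> ROI:
    """ROI covering the fur-free ear patch (interior to the body)."""
    a = config.animals[animal_idx]
    cr, cc = _center_px(config, animal_idx)
    er = cr + a.ear_offset_mm[1] * config.px_per_mm
    ec = cc + a.ear_offset_mm[0] * config.px_per_mm
    rad = a.ear_radius_mm * config.px_per_mm + margin_px
    return ROI(
        int(np.floor(er - rad)), int(np.floor(ec - rad)),
        int(np.ceil(er + rad)), int(np.ceil(ec + rad)), label="ear",
    )


def eye_roi(config: SceneConfig, animal_idx: int = 0, margin_px: int = 0) -> ROI:
    a = config.animals[animal_idx]
    cr, cc = _center_px(config, animal_idx)
    er = cr + a.eye_offset_mm[1] * config.px_per_mm
    ec = cc + a.eye_offset_mm[0] * config.px_per_mm
    rad = a.eye_radius_mm * config.px_per_mm + margin_px
    return ROI(
        int(np.floor(er - rad)), int(np.floor(ec - rad)),
        int(np.ceil(er + rad)), int(np.ceil(ec + rad)), label="eye",
    )


def edge_roi(config: SceneConfig, animal_idx: int = 0, half_width_px: int = 15,
             half_height_px: int = 6) -> ROI:
    """ROI straddling the animal's outer edge at the top of the minor axis,
    where the breathing boundary motion is expressed."""
    a = config.animals[animal_idx]
    cr, cc = _center_px(config, animal_idx)
    boundary_r = cr - a.body_axes_mm[1] * config.px_per_mm
    return ROI(
        int(boundary_r - half_height_px), int(cc - half_width_px),
        int(boundary_r + half_height_px), int(cc + half_width_px), label="edge",
    )


def reference_roi(config: SceneConfig, size_px: int = 20) -> ROI:
    """Animal-free reference ROI in the cage corner."""
    return ROI(2, 2, 2 + size_px, 2 + size_px, label="reference")


def simulate_activity_speeds(
    days: float = 3.0,
    step_min: float = 5.0,
    active_speed: float = 40.0,
    rest_speed: float = 5.0,
    noise_sd: float = 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Locomotion-speed series (mm/s) alternating 12 h active / 12 h rest.

    Emulates the 12-hour light-dark cycle of housed mice, downsampled to one
    sample per ``step_min`` minutes.  Returns (timestamps_s, speeds).
    """
    rng = np.random.default_rng(seed)
    t_s = np.arange(0.0, days * 86400.0, step_min * 60.0)
    phase = (t_s / 3600.0) % 24.0
    speeds = np.where(phase < 12.0, active_speed, rest_speed).astype(np.float64)
    speeds = np.clip(speeds + rng.normal(0.0, noise_sd, size=t_s.size), 0.0, None)
    return t_s, speeds


def simulate_to_dir(config: SceneConfig, out_dir: str | Path,
                    allow_alias: bool = False) -> Path:
    """Render both modalities plus ground truth into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_sequence(render_nir(config, allow_alias), out_dir / "nir")
    save_sequence(render_thermal(config, allow_alias), out_dir / "thermal")
    (out_dir / "ground_truth.json").write_text(ground_truth(config).to_json())
    (out_dir / "scene.json").write_text(config.to_json())
    return out_dir
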