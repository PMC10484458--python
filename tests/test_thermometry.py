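"""Thermal segmentation, surface temperature, eye core proxy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cagevitals import synthcage as sc
from cagevitals.errors import NoAnimalError, ResolutionError
from cagevitals.framestore import Frame, Modality, ROI
from cagevitals.thermometry import (
    BodyMask,
    ReadingKind,
    eye_core_proxy,
    segment_animal,
    surface_temperature,
)


def _thermal_frame(px):
    return Frame(np.asarray(px, dtype=np.float64), 0, Modality.THERMAL)


def _true_body_mask(cfg, shape):
    """Oracle: rasterize the configured body ellipse directly."""
    a = cfg.animals[0]
    gt = sc.ground_truth(cfg)
    x_mm, y_mm = gt.positions_mm[0, 0]
    ppm = cfg.px_per_mm
    rows = np.arange(shape[0])[:, None] - y_mm * ppm
    cols = np.arange(shape[1])[None, :] - x_mm * ppm
    return (rows / (a.body_axes_mm[1] * ppm)) ** 2 + (
        cols / (a.body_axes_mm[0] * ppm)
    ) ** 2 <= 1.0


class TestSegmentation:
    def test_empty_cage_gives_empty_mask(self):
        frame = _thermal_frame(np.full((40, 60), 22.0))
        assert not segment_animal(frame, 30.0).mask.any()

    def test_body_mask_overlaps_true_ellipse(self, small_thermal_cfg, small_thermal):
        frame = small_thermal.frames[0]
        mask = segment_animal(frame, 30.0)
        truth = _true_body_mask(small_thermal_cfg, frame.shape)
        inter = (mask.mask & truth).sum()
        union = (mask.mask | truth).sum()
        assert inter / union >= 0.9

    def test_two_animals_give_two_components(self):
        cfg = sc.SceneConfig(
            cage_mm=(300.0, 150.0),
            px_per_mm=1.0,
            fps=4.0,
            duration_s=0.5,
            seed=41,
            animals=[
                sc.AnimalConfig(rr_bpm=100.0, trajectory=[(0.0, 70.0, 75.0)]),
                sc.AnimalConfig(rr_bpm=100.0, trajectory=[(0.0, 230.0, 75.0)]),
            ],
        )
        th = sc.render_thermal(cfg)
        assert segment_animal(th.frames[0], 30.0).n_components == 2

    def test_small_noise_specks_removed(self):
        px = np.full((40, 60), 22.0)
        px[5, 5] = 37.0  # single hot pixel
        assert not segment_animal(_thermal_frame(px), 30.0).mask.any()


class TestSurfaceTemperature:
    def test_noiseless_interior_recovers_body_temperature(self, quiet_cfg):
        th = sc.render_thermal(quiet_cfg)
        frame = th.frames[0]
        # interior-only mask (threshold close to body temperature) excludes
        # the blended edge-gradient pixels
        interior = segment_animal(frame, 36.5)
        reading = surface_temperature(frame, interior)
        assert reading.kind is ReadingKind.SURFACE_MEAN
        assert reading.value_c == pytest.approx(37.0, abs=0.05)
        # the default mask includes edge-gradient pixels, biasing slightly low
        default = surface_temperature(frame, segment_animal(frame, 30.0))
        assert default.value_c == pytest.approx(37.0, abs=0.6)
        assert default.value_c < reading.value_c
        assert default.valid

    def test_single_pixel_mask_returns_that_pixel(self):
        px = np.full((10, 10), 22.0)
        px[4, 4] = 35.2
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 4] = True
        reading = surface_temperature(_thermal_frame(px), BodyMask(mask, 30.0))
        assert reading.value_c == pytest.approx(35.2)
        assert reading.n_pixels == 1

    def test_out_of_range_artifact_invalidates_reading(self):
        px = np.full((10, 10), 37.0)
        px[0, 0] = 75.0  # outside the camera's +20..+60 degC contract
        mask = np.ones((10, 10), dtype=bool)
        reading = surface_temperature(_thermal_frame(px), BodyMask(mask, 30.0))
        assert not reading.valid

    def test_empty_mask_raises(self):
        frame = _thermal_frame(np.full((10, 10), 22.0))
        with pytest.raises(NoAnimalError):
            surface_temperature(frame, BodyMask(np.zeros((10, 10), dtype=bool), 30.0))

    @settings(deadline=None, max_examples=20)
    @given(offset=st.floats(-1.5, 1.5), seed=st.integers(0, 2**16))
    def test_constant_offset_shifts_reading_by_offset(self, offset, seed):
        """Offsetting pixels and threshold together leaves the mask unchanged
        and shifts the reading by exactly the offset."""
        rng = np.random.default_rng(seed)
        px = np.full((30, 40), 22.0) + rng.normal(0, 0.05, (30, 40))
        px[10:20, 10:25] += 15.0
        m0 = segment_animal(_thermal_frame(px), 30.0)
        m1 = segment_animal(_thermal_frame(px + offset), 30.0 + offset)
        np.testing.assert_array_equal(m0.mask, m1.mask)
        r0 = surface_temperature(_thermal_frame(px), m0)
        r1 = surface_temperature(_thermal_frame(px + offset), m1)
        assert r1.value_c - r0.value_c == pytest.approx(offset, abs=1e-9)


class TestEyeCoreProxy:
    def test_recovers_configured_eye_temperature(self, small_thermal_cfg, small_thermal):
        reading = eye_core_proxy(small_thermal.frames[0], sc.eye_roi(small_thermal_cfg))
        assert reading.kind is ReadingKind.EYE_CORE_PROXY
        assert reading.value_c == pytest.approx(38.5, abs=0.2)

    def test_eye_is_warmer_than_surface(self, small_thermal_cfg, small_thermal):
        frame = small_thermal.frames[0]
        eye = eye_core_proxy(frame, sc.eye_roi(small_thermal_cfg))
        surf = surface_temperature(frame, segment_animal(frame, 30.0))
        assert eye.value_c > surf.value_c

    def test_sub_resolution_roi_raises(self, small_thermal):
        with pytest.raises(ResolutionError, match="px/mm"):
            eye_core_proxy(small_thermal.frames[0], ROI(10, 10, 11, 11))

    def test_uniform_roi_returns_its_temperature(self):
        frame = _thermal_frame(np.full((10, 10), 37.0))
        reading = eye_core_proxy(frame, ROI(2, 2, 6, 6))
        assert reading.value_c == pytest.approx(37.0)

    def test_recovery_across_seeds(self):
        """Configured temperatures recovered within tolerance across seeds."""
        for seed in range(5):
            cfg = sc.SceneConfig(
                cage_mm=(200.0, 150.0), px_per_mm=1.0, fps=4.0, duration_s=0.5,
                seed=seed, animals=[sc.AnimalConfig(rr_bpm=100.0)],
            )
            th = sc.render_thermal(cfg)
            frame = th.frames[0]
            surf = surface_temperature(frame, segment_animal(frame, 30.0))
            eye = eye_core_proxy(frame, sc.eye_roi(cfg))
            assert surf.value_c == pytest.approx(37.0, abs=0.3)
            assert eye.value_c == pytest.approx(38.5, abs=0.2)
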