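"""Synthetic cage-scene generator: determinism, geometry, signal placement."""

import numpy as np
import pytest
from scipy import signal as sps

from cagevitals import synthcage as sc
from cagevitals.errors import AliasingError, ValidationError
from cagevitals.framestore import mean_trace


class TestDeterminism:
    def test_same_seed_is_bit_identical(self):
        cfg = sc.SceneConfig(seed=11, duration_s=1.0)
        a = sc.render_nir(cfg)
        b = sc.render_nir(cfg)
        np.testing.assert_array_equal(a.pixel_array(), b.pixel_array())
        np.testing.assert_array_equal(a.timestamps_us, b.timestamps_us)
        ta = sc.render_thermal(cfg)
        tb = sc.render_thermal(cfg)
        np.testing.assert_array_equal(ta.pixel_array(), tb.pixel_array())

    def test_no_modulation_no_noise_gives_identical_frames(self, quiet_cfg):
        nir = sc.render_nir(quiet_cfg)
        first = nir.frames[0].pixels
        for f in nir.frames[1:]:
            np.testing.assert_array_equal(f.pixels, first)


class TestThermalScene:
    def test_interior_body_pixels_at_body_temperature(self, quiet_cfg):
        th = sc.render_thermal(quiet_cfg)
        px = th.frames[0].pixels
        gt = sc.ground_truth(quiet_cfg)
        x_mm, y_mm = gt.positions_mm[0, 0]
        r = int(y_mm * quiet_cfg.px_per_mm)
        c = int(x_mm * quiet_cfg.px_per_mm)
        np.testing.assert_allclose(px[r - 2 : r + 2, c - 2 : c + 2], 37.0, atol=0.01)
        # background away from the animal
        assert px[2, 2] == pytest.approx(22.0, abs=0.01)

    def test_eye_patch_is_hottest_region(self, small_thermal):
        assert float(small_thermal.frames[0].pixels.max()) == pytest.approx(38.5, abs=0.1)

    def test_stationary_animal_centroid_constant(self, small_thermal):
        centroids = []
        for f in small_thermal.frames:
            mask = f.pixels > 30.0
            rows, cols = np.nonzero(mask)
            centroids.append((rows.mean(), cols.mean()))
        centroids = np.asarray(centroids)
        assert np.ptp(centroids, axis=0).max() < 0.1

    def test_moving_animal_centroids_match_ground_truth(self):
        cfg = sc.SceneConfig(
            seed=4,
            duration_s=4.0,
            fps=10.0,
            animals=[
                sc.AnimalConfig(
                    rr_bpm=100.0,
                    trajectory=[(0.0, 150.0, 200.0), (4.0, 350.0, 200.0)],
                )
            ],
        )
        th = sc.render_thermal(cfg)
        gt = sc.ground_truth(cfg)
        ppm = cfg.px_per_mm
        for i, f in enumerate(th.frames):
            mask = f.pixels > 30.0
            rows, cols = np.nonzero(mask)
            x_mm, y_mm = gt.positions_mm[0, i]
            assert abs(cols.mean() - x_mm * ppm) <= 1.0
            assert abs(rows.mean() - y_mm * ppm) <= 1.0


class TestGroundTruth:
    def test_stationary_positions_all_equal(self, quiet_cfg):
        gt = sc.ground_truth(quiet_cfg)
        assert np.ptp(gt.positions_mm[0], axis=0).max() == 0.0

    def test_two_waypoint_path_interpolates_midpoint(self):
        cfg = sc.SceneConfig(
            duration_s=10.0,
            fps=2.0,
            animals=[
                sc.AnimalConfig(trajectory=[(0.0, 100.0, 100.0), (10.0, 300.0, 200.0)])
            ],
        )
        gt = sc.ground_truth(cfg)
        mid = gt.positions_mm[0][10]  # frame at t = 5 s
        np.testing.assert_allclose(mid, [200.0, 150.0], atol=1e-6)

    def test_position_count_matches_frame_count(self, default_cfg):
        gt = sc.ground_truth(default_cfg)
        assert gt.positions_mm.shape == (1, 600, 2)


class TestSignalPlacement:
    def test_noiseless_ear_trace_power_concentrates_at_hr(self):
        """With zero noise, all non-DC power of the ear trace sits at hr_bpm
        (plus leakage-adjacent bins)."""
        cfg = sc.SceneConfig(
            seed=0,
            duration_s=5.0,
            sensor_noise_sd=0.0,
            animals=[sc.AnimalConfig(hr_bpm=480.0, breath_amplitude_px=0.0)],
        )
        nir = sc.render_nir(cfg)
        trace = mean_trace(nir, sc.ear_roi(cfg))
        x = trace.values - trace.values.mean()
        freq, power = sps.periodogram(x, fs=40.0, window="hann")
        freq_bpm = freq * 60.0
        peak_bin = int(np.argmax(power))
        assert freq_bpm[peak_bin] == pytest.approx(480.0, abs=60.0 / 5.0)
        near = np.abs(freq_bpm - freq_bpm[peak_bin]) <= 2 * 60.0 / 5.0
        assert power[~near].sum() < 0.01 * power.sum()

    def test_ambient_lighting_raises_spectral_noise_floor(self):
        """The broadband ambient term raises the median spectral noise floor."""
        floors = {False: [], True: []}
        for seed in range(5):
            for ambient in (False, True):
                cfg = sc.SceneConfig(
                    seed=seed, duration_s=5.0, ambient_lighting=ambient
                )
                nir = sc.render_nir(cfg)
                trace = mean_trace(nir, sc.reference_roi(cfg))
                x = trace.values - trace.values.mean()
                _, power = sps.periodogram(x, fs=40.0, window="hann")
                floors[ambient].append(np.median(power[1:]))
        assert np.median(floors[True]) > np.median(floors[False])

    def test_rates_above_nyquist_refused_unless_allowed(self):
        cfg = sc.SceneConfig(
            fps=20.0, duration_s=1.0, animals=[sc.AnimalConfig(hr_bpm=700.0)]
        )
        with pytest.raises(AliasingError):
            sc.render_nir(cfg)
        seq = sc.render_nir(cfg, allow_alias=True)
        assert len(seq) == 20


class TestConfigValidation:
    def test_hr_must_exceed_rr(self):
        with pytest.raises(ValidationError):
            sc.AnimalConfig(hr_bpm=100.0, rr_bpm=150.0)

    def test_temperatures_must_be_in_camera_range(self):
        with pytest.raises(ValidationError):
            sc.AnimalConfig(body_temp_c=70.0)

    def test_config_json_round_trip(self, default_cfg):
        restored = sc.SceneConfig.from_json(default_cfg.to_json())
        assert restored == default_cfg

    def test_simulate_to_dir_writes_both_modalities(self, tmp_path):
        cfg = sc.SceneConfig(seed=9, duration_s=0.5, fps=4.0,
                             cage_mm=(200.0, 150.0), px_per_mm=0.5,
                             animals=[sc.AnimalConfig(rr_bpm=100.0,
                                                      ppg_amplitude=0.0)])
        out = sc.simulate_to_dir(cfg, tmp_path / "scene")
        assert (out / "nir" / "frames.tif").exists()
        assert (out / "thermal" / "frames.tif").exists()
        assert (out / "ground_truth.json").exists()
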