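"""Shared fixtures: synthetic scenes rendered once per session."""

import pytest

from cagevitals import synthcage as sc


@pytest.fixture(scope="session")
def default_cfg() -> sc.SceneConfig:
    """Standard 15 s, 40 fps scene: one mouse, HR 500/min, RR 150/min."""
    return sc.SceneConfig(seed=1)


@pytest.fixture(scope="session")
def default_nir(default_cfg):
    return sc.render_nir(default_cfg)


@pytest.fixture(scope="session")
def quiet_cfg() -> sc.SceneConfig:
    """Noiseless, modulation-free short scene (frames should be identical)."""
    return sc.SceneConfig(
        seed=2,
        duration_s=2.0,
        sensor_noise_sd=0.0,
        thermal_noise_sd_c=0.0,
        animals=[
            sc.AnimalConfig(ppg_amplitude=0.0, breath_amplitude_px=0.0)
        ],
    )


@pytest.fixture(scope="session")
def small_thermal_cfg() -> sc.SceneConfig:
    """Small 1 px/mm thermal scene (eye resolvable), cheap to render."""
    return sc.SceneConfig(
        cage_mm=(200.0, 150.0),
        px_per_mm=1.0,
        fps=4.0,
        duration_s=1.0,
        seed=3,
        animals=[sc.AnimalConfig(rr_bpm=100.0, hr_bpm=500.0)],
    )


@pytest.fixture(scope="session")
def small_thermal(small_thermal_cfg):
    return sc.render_thermal(small_thermal_cfg)
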