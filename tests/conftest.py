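"""Shared fixtures: environments, geometries and rendered synthetic scenes.

Scene renders are session-scoped — they are the expensive part of the
suite and are pure functions of their seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from nbhfsonar import interface
from nbhfsonar import synthetic_scene as ss
from nbhfsonar.core import ArrayGeometry, EnvironmentProfile


@pytest.fixture(scope="session")
def bc_env() -> EnvironmentProfile:
    """British Columbia recording conditions (9.2 °C, 33.9 ‰)."""
    return EnvironmentProfile(temperature=9.2, salinity=33.9, depth=5.0)


@pytest.fixture(scope="session")
def dk_env() -> EnvironmentProfile:
    """Danish recording conditions (15 °C, 20 ‰)."""
    return EnvironmentProfile(temperature=15.0, salinity=20.0, depth=5.0)


@pytest.fixture(scope="session")
def geometry() -> ArrayGeometry:
    return ArrayGeometry.default_vertical()


def make_scan_source(
    range_m: float,
    depth_m: float = 4.25,
    fc_khz: float = 137.0,
    duration_10db_us: float = 104.0,
    sl_pp_db: float = 183.0,
    aperture_cm: float = 10.0,
    n_clicks: int = 7,
    ici_ms: float = 60.0,
) -> ss.ClickSourceSpec:
    """A source whose beam sweeps across (and beyond) the array.

    With 7 clicks the sweep aims at z = 1.0 … 7.5 m; the central click
    points exactly at the hydrophone at 4.25 m (channel 2), while the
    first and last clicks aim past the array ends and are received
    weaker everywhere — a textbook scan with one truly on-axis click.
    """
    return ss.ClickSourceSpec(
        position=(range_m, 0.0, depth_m),
        fc_khz=fc_khz,
        duration_10db_us=duration_10db_us,
        sl_pp_db=sl_pp_db,
        aperture_cm=aperture_cm,
        ici_sequence_ms=(ici_ms,) * (n_clicks - 1),
        aim_sweep=((0.0, 0.0, 1.0), (0.0, 0.0, 7.5)),
    )


def make_scene(
    sources,
    env: EnvironmentProfile,
    geometry: ArrayGeometry,
    noise_spectral_level: float | None = None,
    seed: int = 7,
    **kwargs,
) -> ss.SceneConfig:
    return ss.SceneConfig(
        geometry=geometry,
        environment=env,
        sources=list(sources),
        noise_spectral_level=noise_spectral_level,
        seed=seed,
        quantize_16bit=kwargs.pop("quantize_16bit", False),
        **kwargs,
    )


@pytest.fixture(scope="session")
def scan_scene_30m(bc_env, geometry) -> ss.SceneConfig:
    """Noiseless single-scan scene: Dall's-type source at 30 m."""
    return make_scene([make_scan_source(30.0)], bc_env, geometry, seed=7)


@pytest.fixture(scope="session")
def scan_recording_30m(scan_scene_30m):
    return ss.render_array_recording(scan_scene_30m)


@pytest.fixture(scope="session")
def pipeline_result_30m(scan_scene_30m, scan_recording_30m):
    cfg = interface.PipelineConfig(scene=scan_scene_30m)
    return interface._analyze_recording(scan_recording_30m, cfg)


@pytest.fixture(scope="session")
def beam_pipeline_frames(bc_env, geometry):
    """Beam samples from noiseless 10 cm piston scans at 12/15/18 m."""
    frames = []
    for i, r in enumerate((12.0, 15.0, 18.0)):
        scene = make_scene([make_scan_source(r)], bc_env, geometry, seed=20 + i)
        rec = ss.render_array_recording(scene)
        res = interface._analyze_recording(
            rec, interface.PipelineConfig(scene=scene)
        )
        frames.append(res["beam"])
    return frames
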