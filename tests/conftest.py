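"""Shared fixtures: small, fast microscope configurations.

Tests use reduced sensors (the physics is resolution-independent) and a
100 nm xy step so stage positions land exactly on pixel centres where that
simplifies ground-truth bookkeeping.
"""

from __future__ import annotations

import numpy as np
import pytest

import simscope as ss


@pytest.fixture
def noiseless_cam():
    return ss.CameraConfig(sensor_px=(200, 150), read_noise_sigma=0.0, shot_noise_scale=0.0)


@pytest.fixture
def noisy_cam():
    return ss.CameraConfig(sensor_px=(200, 150))


@pytest.fixture
def smear():
    return ss.blood_smear_field(seed=3, extent_um=(300, 300))


@pytest.fixture
def px_stage():
    """Stage whose xy step equals the default 100 nm pixel pitch."""
    return ss.StageState(step_size_nm=[100, 100, 50])


def make_scope(
    specimen=None,
    camera=None,
    optics=None,
    stage=None,
    seed=0,
    **kwargs,
) -> ss.VirtualMicroscope:
    return ss.VirtualMicroscope(
        specimen=specimen or ss.blood_smear_field(seed=3, extent_um=(300, 300)),
        optics=optics or ss.OpticsConfig(),
        camera=camera or ss.CameraConfig(sensor_px=(200, 150)),
        stage=stage or ss.StageState(step_size_nm=[100, 100, 50]),
        seed=seed,
        **kwargs,
    )


def grab_tiles(scope, xy_list, jitter_nm=None, rng=None):
    """Capture a list of Tiles at given (grid_index, (x, y)) sites."""
    tiles = []
    for k, (gi, (x, y)) in enumerate(xy_list):
        jx = jy = 0.0
        if jitter_nm:
            jx, jy = rng.uniform(-jitter_nm, jitter_nm, 2)
        scope.move_to(x_nm=x + jx, y_nm=y + jy)
        frame = scope.capture()
        tiles.append(
            ss.Tile(
                frame=frame,
                grid_index=gi,
                nominal_xy_nm=(x, y),
                z_offset_nm=0.0,
                capture_z_nm=0.0,
                site_index=k,
                is_central=True,
            )
        )
    return tiles


def grid_2x2(spacing_x_nm=16000, spacing_y_nm=12000):
    sites = []
    for j, y in enumerate((-spacing_y_nm / 2, spacing_y_nm / 2)):
        for i, x in enumerate((-spacing_x_nm / 2, spacing_x_nm / 2)):
            sites.append(((i, j), (x, y)))
    return sites
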