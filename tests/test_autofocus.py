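import numpy as np
import pytest

import simscope as ss
from simscope.autofocus import _parabolic_vertex, laplacian_sharpness

from conftest import make_scope


def test_laplacian_sharpness_orders_blur():
    rng = np.random.default_rng(0)
    sharp = rng.integers(0, 255, (64, 64)).astype(np.uint8)
    from scipy.ndimage import gaussian_filter

    blurred = gaussian_filter(sharp.astype(float), 2.0)
    assert laplacian_sharpness(sharp) > laplacian_sharpness(blurred)
    assert laplacian_sharpness(np.full((64, 64), 100, dtype=np.uint8)) == 0.0


def test_parabolic_vertex():
    z = np.array([-1.0, 0.0, 1.0])
    s = np.array([1.0, 2.0, 1.0])
    assert _parabolic_vertex(z, s) == pytest.approx(0.0)
    s = np.array([1.0, 2.0, 1.5])
    assert 0.0 < _parabolic_vertex(z, s) < 1.0


def test_sweep_finds_focus():
    scope = make_scope(seed=1)
    result = ss.autofocus_sweep(scope, (-5000, 5000), n_points=15)
    assert result.method == "laplacian_sweep"
    assert not result.at_boundary
    assert abs(result.best_z_nm - scope.true_focus_z_nm()) <= scope.optics.depth_of_focus_nm()
    assert len(result.samples) == 15
    assert scope.position_nm[2] == pytest.approx(result.best_z_nm, abs=25)


def test_sweep_is_relative_to_current_z():
    spec = ss.blood_smear_field(seed=3, extent_um=(300, 300), focal_surface=(0, 0, 3000.0))
    scope = make_scope(specimen=spec, seed=1)
    scope.move_to(z_nm=2_500)
    result = ss.autofocus_sweep(scope, (-5000, 5000), n_points=15)
    assert abs(result.best_z_nm - 3000.0) <= scope.optics.depth_of_focus_nm()


def test_sweep_boundary_flag():
    spec = ss.blood_smear_field(seed=3, extent_um=(300, 300), focal_surface=(0, 0, 5000.0))
    # noiseless camera: far from focus the Laplacian score of a noisy frame
    # is dominated by pixel noise, which would make the curve non-monotonic
    cam = ss.CameraConfig(sensor_px=(200, 150), read_noise_sigma=0.0, shot_noise_scale=0.0)
    scope = make_scope(specimen=spec, camera=cam, seed=1)
    result = ss.autofocus_sweep(scope, (-3000, 3000), n_points=7)
    assert result.at_boundary
    assert result.best_z_nm == pytest.approx(3000.0)


def test_sweep_validates_points():
    with pytest.raises(ValueError):
        ss.autofocus_sweep(make_scope(), (-1000, 1000), n_points=2)


def test_jpeg_fast_finds_focus():
    scope = make_scope(seed=2)
    result = ss.jpeg_fast_autofocus(scope, (-5000, 5000), speed_nm_per_s=20_000)
    assert result.method == "jpeg_fast"
    spacing = 20_000 / scope.camera.frame_rate_hz
    assert abs(result.best_z_nm - scope.true_focus_z_nm()) <= spacing
    assert all(s.frame_bytes > 0 for s in result.samples)


def test_jpeg_fast_too_fast_raises():
    scope = make_scope()
    with pytest.raises(ss.FocusError, match="reduce speed"):
        ss.jpeg_fast_autofocus(scope, (-1000, 1000), speed_nm_per_s=500_000)


def test_jpeg_fast_flat_scene_raises():
    scope = make_scope(specimen=ss.flat_field(intensity=0.8, extent_um=(300, 300)))
    with pytest.raises(ss.FocusError, match="no focus found"):
        ss.jpeg_fast_autofocus(scope, (-5000, 5000), speed_nm_per_s=20_000)


def test_methods_agree_within_sweep_spacing():
    n_points = 15
    lo, hi = -5000.0, 5000.0
    spacing = (hi - lo) / (n_points - 1)
    sweep = ss.autofocus_sweep(make_scope(seed=5), (lo, hi), n_points=n_points)
    fast = ss.jpeg_fast_autofocus(make_scope(seed=5), (lo, hi), speed_nm_per_s=20_000)
    assert abs(sweep.best_z_nm - fast.best_z_nm) <= spacing


def test_jpeg_latency_shifts_estimate():
    a = ss.jpeg_fast_autofocus(make_scope(seed=2), (-5000, 5000), speed_nm_per_s=20_000)
    b = ss.jpeg_fast_autofocus(
        make_scope(seed=2), (-5000, 5000), speed_nm_per_s=20_000, latency_s=0.1
    )
    assert b.best_z_nm == pytest.approx(a.best_z_nm - 0.1 * 20_000, abs=1.0)
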