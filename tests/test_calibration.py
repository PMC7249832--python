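import numpy as np
import pytest

import simscope as ss
from simscope.calibration import EdgeNotFoundError, detect_edge_points
from simscope.optics import FWHM_PER_SIGMA

from conftest import make_scope


def edge_scope(fwhm_nm=480.0, angle_deg=1.0, noise=True, sensor=(400, 300), seed=42):
    cam = ss.CameraConfig(
        sensor_px=sensor,
        read_noise_sigma=1.0 if noise else 0.0,
        shot_noise_scale=0.2 if noise else 0.0,
    )
    return make_scope(
        specimen=ss.knife_edge_field(angle_deg=angle_deg, extent_um=(300, 300)),
        optics=ss.OpticsConfig(psf_fwhm_nm=fwhm_nm),
        camera=cam,
        seed=seed,
    )


# -- edge detection / ESF ---------------------------------------------------


def test_detect_edge_points_near_vertical():
    frame = edge_scope(noise=False).capture()
    pts = detect_edge_points(frame.pixels)
    assert len(pts) >= 0.8 * frame.pixels.shape[0]
    # 1 degree tilt: x drifts by about tan(1 deg) px per row
    slope = np.polyfit(pts[:, 1], pts[:, 0], 1)[0]
    assert slope == pytest.approx(-np.tan(np.deg2rad(1.0)), abs=5e-3)


def test_detect_edge_requires_contrast():
    with pytest.raises(EdgeNotFoundError):
        detect_edge_points(np.full((50, 60), 128, dtype=np.uint8))


def test_edge_profile_monotone_plateaus():
    frame = edge_scope().capture()
    prof = ss.extract_edge_profile(frame.pixels, 100.0)
    assert prof.n_rows_used >= 240
    # normalized: dark plateau near 0, bright plateau near 1
    assert abs(float(np.median(prof.values[:10]))) < 0.05
    assert abs(float(np.median(prof.values[-10:])) - 1.0) < 0.05
    assert prof.pitch_nm == 100.0


# -- PSF recovery -----------------------------------------------------------


@pytest.mark.parametrize("true_fwhm", [400.0, 480.0, 700.0])
def test_psf_fwhm_recovery_noise_free(true_fwhm):
    frame = edge_scope(fwhm_nm=true_fwhm, noise=False).capture()
    est = ss.psf_from_edge(ss.extract_edge_profile(frame.pixels, 100.0))
    assert est.fwhm_nm == pytest.approx(true_fwhm, rel=0.05)


def test_psf_fwhm_recovery_with_noise_across_seeds():
    for seed in (42, 7, 1):
        frame = edge_scope(seed=seed).capture()
        est = ss.psf_from_edge(ss.extract_edge_profile(frame.pixels, 100.0))
        assert est.fwhm_nm == pytest.approx(480.0, rel=0.05)


def test_sqrt_first_inverts_coherent_model():
    frame = edge_scope(noise=False).capture()
    prof = ss.extract_edge_profile(frame.pixels, 100.0)
    coherent = ss.psf_from_edge(prof, sqrt_first=True)
    wrong = ss.psf_from_edge(prof, sqrt_first=False)
    # treating the coherent edge as incoherent mis-estimates the width
    assert abs(coherent.fwhm_nm - 480.0) < abs(wrong.fwhm_nm - 480.0)


def test_resolution_limited_flag():
    frame = edge_scope(fwhm_nm=480.0, noise=False).capture()
    est = ss.psf_from_edge(ss.extract_edge_profile(frame.pixels, 100.0))
    assert not est.resolution_limited  # 480 nm >= 2 x 100 nm pitch


# -- sampling adequacy ------------------------------------------------------


def test_sampling_check_bayer_doubles_pitch():
    v = ss.sampling_check(100.0, 480.0, bayer_enabled=True)
    assert v.effective_pitch_nm == 200.0
    assert v.adequately_sampled
    mono = ss.sampling_check(100.0, 480.0, bayer_enabled=False)
    assert mono.effective_pitch_nm == 100.0
    coarse = ss.sampling_check(300.0, 480.0, bayer_enabled=True)
    assert not coarse.adequately_sampled
    with pytest.raises(ValueError):
        ss.sampling_check(-1.0, 480.0, False)


# -- distortion -------------------------------------------------------------


def _distortion_scope(k, seed=7):
    return make_scope(
        specimen=ss.knife_edge_field(angle_deg=1.0, extent_um=(300, 300)),
        optics=ss.OpticsConfig(distortion_k=k),
        camera=ss.CameraConfig(sensor_px=(400, 300)),
        seed=seed,
    )


def test_distortion_scan_recovers_injected_k():
    fit = ss.distortion_scan(_distortion_scope(0.02), n_positions=9)
    assert fit.k == pytest.approx(0.02, abs=0.002)
    assert fit.n_lines == 9


def test_distortion_free_reports_near_zero():
    fit = ss.distortion_scan(_distortion_scope(0.0), n_positions=9)
    assert fit.max_fractional_displacement_pct < 0.1


def test_estimate_distortion_needs_enough_lines():
    pts = [np.column_stack([np.full(50, 10.0), np.arange(50.0)])]
    with pytest.raises(ValueError, match="at least 5"):
        ss.estimate_distortion(pts * 4, (100, 80))


def test_estimate_distortion_degenerate_geometry():
    # vertical lines all through the image centre carry no radial signal
    y = np.arange(80.0)
    pts = [np.column_stack([np.full(80, 49.5 + eps), y]) for eps in (0, 0.1, -0.1, 0.05, -0.05)]
    with pytest.raises(ValueError, match="degenerate"):
        ss.estimate_distortion(pts, (100, 80))


# -- lens shading -----------------------------------------------------------


def shading_scope(falloff=0.7, noise=True):
    cam = ss.CameraConfig(
        sensor_px=(320, 240),
        read_noise_sigma=1.0 if noise else 0.0,
        shot_noise_scale=0.2 if noise else 0.0,
    )
    return make_scope(
        specimen=ss.flat_field(intensity=0.7, extent_um=(300, 300)),
        optics=ss.OpticsConfig(vignetting_falloff=falloff),
        camera=cam,
        seed=11,
    )


def test_shading_table_shape_and_gain_range():
    table = ss.build_shading_table(shading_scope().capture().pixels, grid_dims=(32, 24))
    assert table.gains.shape == (24, 32, 1)
    assert table.gains.min() == pytest.approx(1.0)
    # corner gain approximates the inverse vignetting model there
    assert table.gains.max() > 1.2


def test_shading_round_trip_flattens_field():
    scope = shading_scope()
    table = ss.build_shading_table(scope.capture().pixels, grid_dims=(32, 24))
    vignetted = scope.capture().pixels  # fresh frame, fresh noise
    corrected, saturated = ss.apply_shading_correction(vignetted, table)
    # flatness judged on cell means (per-pixel RMS would measure shot noise)
    h, w = corrected.shape
    cells = corrected.reshape(24, h // 24, 32, w // 32).mean(axis=(1, 3))
    assert cells.std() / cells.mean() < 0.01
    assert saturated == 0


def test_shading_insufficient_illumination():
    img = np.full((240, 320), 200.0)
    img[:10, :10] = 1.0
    with pytest.raises(ValueError, match="insufficient illumination"):
        ss.build_shading_table(img)


# -- pixel size -------------------------------------------------------------


def test_pixel_size_calibration():
    scope = make_scope(
        specimen=ss.grid_field(pitch_um=10.0, line_width_um=2.0, extent_um=(300, 300)),
        camera=ss.CameraConfig(sensor_px=(400, 300)),
    )
    cal = ss.calibrate_pixel_size(scope.capture().pixels, known_pitch_um=10.0)
    assert cal.nm_per_px == pytest.approx(100.0, rel=0.01)
    assert cal.fov_um[0] == pytest.approx(40.0, rel=0.01)


def test_pixel_size_requires_periodic_target():
    flat = np.full((100, 120), 128, dtype=np.uint8)
    with pytest.raises(ValueError, match="no periodic peak"):
        ss.calibrate_pixel_size(flat, 10.0)
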