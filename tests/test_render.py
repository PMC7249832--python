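import numpy as np
import pytest

import simscope as ss
from simscope.stage import move_to


def test_render_is_deterministic_in_seed(smear, noisy_cam, px_stage):
    a = ss.render_frame(px_stage, ss.OpticsConfig(), smear, noisy_cam, seed=[7, 0])
    b = ss.render_frame(px_stage, ss.OpticsConfig(), smear, noisy_cam, seed=[7, 0])
    c = ss.render_frame(px_stage, ss.OpticsConfig(), smear, noisy_cam, seed=[7, 1])
    assert np.array_equal(a.pixels, b.pixels)
    assert not np.array_equal(a.pixels, c.pixels)


def test_fov_exceeding_specimen_raises(noiseless_cam, px_stage):
    tiny = ss.blood_smear_field(seed=0, extent_um=(10, 10))
    with pytest.raises(ValueError, match="smaller than the field of view"):
        ss.render_frame(px_stage, ss.OpticsConfig(), tiny, noiseless_cam)


def test_translation_moves_image_by_whole_pixels(smear, noiseless_cam, px_stage):
    opt = ss.OpticsConfig()
    a = ss.render_frame(px_stage, opt, smear, noiseless_cam).pixels
    shifted = move_to(px_stage, [500.0, 0.0, 0.0])  # +5 px in x
    b = ss.render_frame(shifted, opt, smear, noiseless_cam).pixels
    # interior columns shift left by 5 px (stage +x moves the view right)
    assert np.array_equal(a[20:-20, 25:-20], b[20:-20, 20:-25])


def test_defocus_blurs(smear, noiseless_cam, px_stage):
    opt = ss.OpticsConfig()
    sharp = ss.render_frame(px_stage, opt, smear, noiseless_cam).pixels
    out = ss.render_frame(move_to(px_stage, [0, 0, 5000]), opt, smear, noiseless_cam).pixels
    assert np.std(np.diff(out.astype(float), axis=1)) < np.std(np.diff(sharp.astype(float), axis=1))


def test_vignetting_darkens_corners(noiseless_cam, px_stage):
    flat = ss.flat_field(intensity=0.8, extent_um=(300, 300))
    opt = ss.OpticsConfig(vignetting_falloff=0.7)
    img = ss.render_frame(px_stage, opt, flat, noiseless_cam).pixels.astype(float)
    centre = img[70:80, 95:105].mean()
    corner = img[:5, :5].mean()
    assert corner / centre == pytest.approx(0.7, abs=0.02)
    assert centre == pytest.approx(0.8 * 255, abs=2)


def test_distortion_bows_straight_edge(noiseless_cam, px_stage):
    from simscope.calibration import detect_edge_points

    edge = ss.knife_edge_field(angle_deg=0.0, extent_um=(300, 300))
    stage = move_to(px_stage, [7000.0, 0.0, 0.0])  # edge off-centre in the frame
    straight = ss.render_frame(stage, ss.OpticsConfig(), edge, noiseless_cam)
    bowed = ss.render_frame(stage, ss.OpticsConfig(distortion_k=0.05), edge, noiseless_cam)
    span = lambda f: np.ptp(detect_edge_points(f.pixels)[:, 0])
    assert span(straight) < 0.5
    assert span(bowed) > 1.0


def test_coherent_vs_incoherent_edge_width(noiseless_cam, px_stage):
    edge = ss.knife_edge_field(angle_deg=0.0, extent_um=(300, 300))
    coh = ss.render_frame(px_stage, ss.OpticsConfig(edge_model="coherent"), edge, noiseless_cam)
    inc = ss.render_frame(px_stage, ss.OpticsConfig(edge_model="incoherent"), edge, noiseless_cam)
    # coherent intensity = (step * amplitude-PSF)^2 differs from the
    # incoherent intensity convolution near the edge
    mid = coh.pixels.shape[0] // 2
    assert not np.array_equal(coh.pixels[mid], inc.pixels[mid])


def test_bayer_halves_channel_sampling(smear, px_stage):
    cam = ss.CameraConfig(
        sensor_px=(200, 150), mono=False, bayer_enabled=True,
        read_noise_sigma=0.0, shot_noise_scale=0.0,
    )
    frame = ss.render_frame(px_stage, ss.OpticsConfig(), smear, cam)
    assert frame.pixels.shape == (150, 200, 3)


def test_frame_metadata(smear, noisy_cam, px_stage):
    stage = move_to(px_stage, [300.0, -200.0, 100.0])
    frame = ss.render_frame(stage, ss.OpticsConfig(), smear, noisy_cam, timestamp_s=4.5)
    assert tuple(frame.commanded_position_nm) == (300.0, -200.0, 100.0)
    assert tuple(frame.true_position_nm) == (300.0, -200.0, 100.0)
    assert frame.timestamp_s == 4.5
    assert frame.compressed_size_bytes > 0
    assert frame.pixel_pitch_nm == 100.0
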