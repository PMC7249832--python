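"""Image formation: specimen + stage + optics + camera -> Frame.

Rendering is a pure function of its inputs and a seed.  The processing order
is: sample the specimen at (distortion-warped) pixel coordinates, blur with
the defocus-dependent Gaussian PSF (amplitude-domain in coherent mode),
apply vignetting, optional Bayer sampling, sensor noise, and 8-bit
quantization; finally the frame is passed once through a JPEG encoder to
populate ``compressed_size_bytes``.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .camera import (
    CameraConfig,
    Frame,
    LUMA_WEIGHTS,
    apply_noise,
    bayer_sample,
    jpeg_size_bytes,
    quantize,
)
from .optics import FWHM_PER_SIGMA, OpticsConfig
from .specimen import SpecimenField
from .stage import StageState


def _undistort_radius(rp: np.ndarray, k: float) -> np.ndarray:
    """Solve r (1 + k r^2) = rp for r (Newton; k is small)."""
    r = rp.copy()
    for _ in range(4):
        f = r * (1 + k * r * r) - rp
        df = 1 + 3 * k * r * r
        r = r - f / df
    return r


def render_frame(
    stage: StageState,
    optics: OpticsConfig,
    specimen: SpecimenField,
    cam: CameraConfig,
    seed: int = 0,
    timestamp_s: float = 0.0,
) -> Frame:
    """Render one frame at the stage's current *physical* position."""
    w, h = cam.sensor_px
    pitch = optics.pixel_pitch_nm
    fov_nm = np.array([w * pitch, h * pitch])
    extent = specimen.extent_nm
    if np.any(extent < fov_nm):
        deficit = np.maximum(fov_nm - extent, 0) / 1e3
        raise ValueError(
            f"specimen extent {specimen.extent_um} um is smaller than the "
            f"field of view {tuple(fov_nm / 1e3)} um (deficit {tuple(deficit)} um)"
        )

    pos = stage.physical_position_nm
    xj = (np.arange(w) - (w - 1) / 2) * pitch
    yi = ((h - 1) / 2 - np.arange(h)) * pitch  # y up, row index down
    xpix, ypix = np.meshgrid(xj, yi)

    half_diag = np.hypot((w - 1) / 2, (h - 1) / 2) * pitch
    rp = np.hypot(xpix, ypix) / half_diag
    if optics.distortion_k != 0.0:
        r = _undistort_radius(rp, optics.distortion_k)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(rp > 0, r / rp, 1.0)
    else:
        scale = 1.0

    u = pos[0] + xpix * scale
    v = pos[1] + ypix * scale
    rgb = specimen.evaluate_rgb(u, v, aa_nm=pitch)

    # collapse to a single channel early when the output is mono: exact for
    # gray-valued specimens and 3x cheaper to blur
    if cam.mono and not cam.bayer_enabled:
        img = (rgb @ LUMA_WEIGHTS)[..., None]
    else:
        img = rgb

    defocus = pos[2] - specimen.focus_z_nm(pos[0], pos[1])
    fwhm = optics.blur_fwhm_nm(defocus)
    sigma_px = fwhm / FWHM_PER_SIGMA / pitch
    if optics.edge_model == "coherent":
        amp = np.sqrt(img)
        amp = gaussian_filter(amp, sigma=(sigma_px, sigma_px, 0), mode="nearest")
        img = amp * amp
    else:
        img = gaussian_filter(img, sigma=(sigma_px, sigma_px, 0), mode="nearest")

    gain = 1.0 - (1.0 - optics.vignetting_falloff) * rp * rp
    img = img * gain[..., None]

    if cam.bayer_enabled:
        img = bayer_sample(img)
        if cam.mono:
            img = (img @ LUMA_WEIGHTS)[..., None]

    counts = img * cam.max_count
    rng = np.random.default_rng(seed)
    counts = apply_noise(counts, cam, rng)
    pixels = quantize(counts, cam)
    if pixels.shape[2] == 1:
        pixels = pixels[..., 0]

    return Frame(
        pixels=pixels,
        true_position_nm=pos.copy(),
        commanded_position_nm=stage.position_nm.copy(),
        timestamp_s=timestamp_s,
        compressed_size_bytes=jpeg_size_bytes(pixels, cam.compression_quality),
        pixel_pitch_nm=pitch,
    )
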