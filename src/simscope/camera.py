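"""Sensor model and the Frame container.

The camera quantizes to 8 bits and optionally applies Bayer-mosaic sampling
(mosaic then bilinear demosaic, halving per-channel sampling density).  Noise
is signal-dependent: Gaussian approximation to shot noise with standard
deviation ``shot_noise_scale * sqrt(counts)`` plus Gaussian read noise, both
in counts.  Every frame is also passed once through a real JPEG encoder so
``compressed_size_bytes`` reflects genuine codec behaviour — sharper frames
compress worse, which is what the fast autofocus exploits.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

#: Rec. 601 luma weights, used wherever RGB is reduced to grayscale.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class CameraConfig:
    sensor_px: tuple[int, int] = (820, 616)  # width, height
    bit_depth: int = 8
    read_noise_sigma: float = 1.0  # counts
    shot_noise_scale: float = 0.2  # counts^0.5 multiplier
    bayer_enabled: bool = False
    mono: bool = True
    compression_quality: int = 85
    frame_rate_hz: float = 30.0
    exposure_s: float = 1 / 30

    def __post_init__(self):
        if self.bit_depth != 8:
            raise ValueError("only 8-bit output is supported")
        w, h = self.sensor_px
        if w < 3 or h < 3:
            raise ValueError("sensor must be at least 3x3 px")

    @property
    def max_count(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def noise_enabled(self) -> bool:
        return self.read_noise_sigma > 0 or self.shot_noise_scale > 0


@dataclass(frozen=True)
class Frame:
    """A rendered image plus its acquisition metadata."""

    pixels: np.ndarray  # uint8, (H, W) or (H, W, 3)
    true_position_nm: np.ndarray
    commanded_position_nm: np.ndarray
    timestamp_s: float = 0.0
    compressed_size_bytes: int = 0
    pixel_pitch_nm: float = float("nan")
    metadata: dict = field(default_factory=dict)

    @property
    def gray(self) -> np.ndarray:
        """Luminance image as float64 in [0, 255]."""
        return to_gray(self.pixels)


def to_gray(pixels: np.ndarray) -> np.ndarray:
    """Convert a frame raster to float luminance (Rec. 601 weights)."""
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr @ LUMA_WEIGHTS
    raise ValueError(f"expected (H, W) or (H, W, 3) raster, got shape {arr.shape}")


def bayer_sample(rgb: np.ndarray) -> np.ndarray:
    """Mosaic an RGB image (RGGB pattern) then demosaic bilinearly.

    This models the halved per-channel sampling density of a colour sensor
    without any demosaic-algorithm sophistication.
    """
    from scipy.ndimage import convolve

    h, w, _ = rgb.shape
    out = np.empty_like(rgb, dtype=float)
    masks = [np.zeros((h, w)) for _ in range(3)]
    masks[0][0::2, 0::2] = 1.0
    masks[1][0::2, 1::2] = 1.0
    masks[1][1::2, 0::2] = 1.0
    masks[2][1::2, 1::2] = 1.0
    kernel = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]]) / 4.0
    for c in range(3):
        sampled = rgb[..., c] * masks[c]
        num = convolve(sampled, kernel, mode="nearest")
        den = convolve(masks[c], kernel, mode="nearest")
        out[..., c] = num / den
    return out


def apply_noise(counts: np.ndarray, cam: CameraConfig, rng: np.random.Generator) -> np.ndarray:
    """Add shot + read noise in counts (Gaussian approximation)."""
    if not cam.noise_enabled:
        return counts
    sigma = np.sqrt(
        (cam.shot_noise_scale**2) * np.clip(counts, 0, None) + cam.read_noise_sigma**2
    )
    return counts + rng.standard_normal(counts.shape) * sigma


def quantize(counts: np.ndarray, cam: CameraConfig) -> np.ndarray:
    return np.clip(np.rint(counts), 0, cam.max_count).astype(np.uint8)


def jpeg_size_bytes(pixels: np.ndarray, quality: int) -> int:
    """Byte length of the frame encoded once as JPEG at ``quality``."""
    img = Image.fromarray(pixels, mode="L" if pixels.ndim == 2 else "RGB")
    buf = io.BytesIO()
    img.save(buf, format="JPEG", quality=int(quality))
    return buf.tell()
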