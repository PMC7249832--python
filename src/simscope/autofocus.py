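"""Image-based autofocus.

Two algorithms are provided:

* :func:`autofocus_sweep` — the stage steps through a set of z positions,
  captures a frame at each, scores it with the variance-like Laplacian
  sharpness metric, and refines the best position with a parabola through
  the three samples around the maximum.  Accurate but requires a full
  move-settle-capture cycle per point.
* :func:`jpeg_fast_autofocus` — sharpness is monitored *while the stage
  moves continuously*, using the storage size of each frame in the
  compressed (MJPEG-style) video stream as a proxy: sharp images hold more
  high-frequency detail and compress worse.  A single continuous pass over
  the range replaces one settle per sample point, which is what makes the
  method an order of magnitude faster on real hardware.

Both approach their final position from the same direction (from below) so
mechanical backlash cannot bias the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve, uniform_filter1d

from .camera import to_gray

LAPLACIAN_KERNEL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


class FocusError(RuntimeError):
    """Raised when an autofocus routine cannot find a focus."""


@dataclass(frozen=True)
class SharpnessSample:
    z_nm: float
    score: float
    frame_bytes: int = 0
    timestamp_s: float = 0.0


@dataclass(frozen=True)
class FocusResult:
    best_z_nm: float
    samples: list[SharpnessSample] = field(default_factory=list)
    method: str = "laplacian_sweep"
    at_boundary: bool = False

    @property
    def scores(self) -> np.ndarray:
        return np.array([s.score for s in self.samples])

    @property
    def z_positions_nm(self) -> np.ndarray:
        return np.array([s.z_nm for s in self.samples])


def laplacian_sharpness(image: np.ndarray) -> float:
    """Mean squared response of the 3x3 discrete Laplacian.

    RGB input is converted to luminance first; only pixels whose 3x3
    neighbourhood lies fully inside the image contribute.  A uniform image
    scores exactly 0.
    """
    gray = to_gray(image)
    if gray.shape[0] < 3 or gray.shape[1] < 3:
        raise ValueError(f"image {gray.shape} smaller than the 3x3 Laplacian kernel")
    resp = convolve(gray, LAPLACIAN_KERNEL, mode="constant")[1:-1, 1:-1]
    return float(np.mean(resp * resp))


def _parabolic_vertex(z: np.ndarray, s: np.ndarray) -> float:
    """Vertex of the parabola through three (z, score) points (equal or not)."""
    denom = (z[0] - z[1]) * (z[0] - z[2]) * (z[1] - z[2])
    if denom == 0:
        return float(z[1])
    a = (z[2] * (s[1] - s[0]) + z[1] * (s[0] - s[2]) + z[0] * (s[2] - s[1])) / denom
    b = (z[2] ** 2 * (s[0] - s[1]) + z[1] ** 2 * (s[2] - s[0]) + z[0] ** 2 * (s[1] - s[2])) / denom
    if a >= 0:  # not a maximum; fall back to the sampled peak
        return float(z[1])
    return float(np.clip(-b / (2 * a), z[0], z[2]))


def autofocus_sweep(
    scope,
    z_range_nm: tuple[float, float] = (-10_000.0, 10_000.0),
    n_points: int = 11,
    approach_overshoot_nm: float = 5_000.0,
) -> FocusResult:
    """Stepped Laplacian-sharpness autofocus.

    ``z_range_nm`` is relative to the current z position.  All positions are
    visited in ascending order after an initial overshoot below the range, so
    every sample (and the final move to the peak) is approached from the same
    direction.  The returned best z is the parabolic refinement through the
    three samples around the arg-max, unless the peak sits at the end of the
    range, in which case ``at_boundary`` is set and no refinement is done.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    z0 = float(scope.position_nm[2])
    zs = np.linspace(z0 + z_range_nm[0], z0 + z_range_nm[1], n_points)

    scope.move_to(z_nm=zs[0] - approach_overshoot_nm)
    samples: list[SharpnessSample] = []
    for z in zs:
        scope.move_to(z_nm=z)
        frame = scope.capture()
        samples.append(
            SharpnessSample(
                z_nm=z,
                score=laplacian_sharpness(frame.pixels),
                frame_bytes=frame.compressed_size_bytes,
                timestamp_s=frame.timestamp_s,
            )
        )

    scores = np.array([s.score for s in samples])
    peak = int(np.argmax(scores))  # ties resolve to the smallest z
    at_boundary = peak in (0, n_points - 1)
    if at_boundary:
        best = float(zs[peak])
    else:
        best = _parabolic_vertex(zs[peak - 1 : peak + 2], scores[peak - 1 : peak + 2])

    scope.move_to(z_nm=best - approach_overshoot_nm)
    scope.move_to(z_nm=best)
    return FocusResult(best_z_nm=best, samples=samples, method="laplacian_sweep", at_boundary=at_boundary)


def jpeg_fast_autofocus(
    scope,
    z_range_nm: tuple[float, float] = (-10_000.0, 10_000.0),
    speed_nm_per_s: float = 20_000.0,
    smooth_window: int = 5,
    flat_fraction: float = 0.05,
    latency_s: float = 0.0,
    approach_overshoot_nm: float = 5_000.0,
) -> FocusResult:
    """Fast autofocus from compressed-frame sizes during continuous motion.

    The stage sweeps the range bottom-to-top in one continuous pass while
    the camera streams; the byte size of each compressed frame is recorded,
    smoothed with a moving average, and the peak frame is mapped back to a z
    position through the constant-velocity time->position model (optionally
    shifted by a camera ``latency_s``).  The stage then returns to that z
    from below.
    """
    z0 = float(scope.position_nm[2])
    z_lo, z_hi = z0 + z_range_nm[0], z0 + z_range_nm[1]
    if z_hi <= z_lo:
        raise ValueError("z range must have positive extent")

    scope.move_to(z_nm=z_lo - approach_overshoot_nm)
    scope.move_to(z_nm=z_lo)
    frames = scope.stream_z(z_lo, z_hi, speed_nm_per_s)
    if len(frames) < 5:
        raise FocusError(
            f"only {len(frames)} frames captured over the range; "
            "reduce speed_nm_per_s so at least 5 frames are acquired"
        )

    sizes = np.array([f.compressed_size_bytes for f in frames], dtype=float)
    window = max(1, min(smooth_window, len(sizes)))
    smoothed = uniform_filter1d(sizes, size=window, mode="nearest")
    if (smoothed.max() - smoothed.min()) < flat_fraction * smoothed.mean():
        raise FocusError(
            "no focus found: compressed frame size is flat across the range "
            f"(relative variation below {flat_fraction:.2%})"
        )

    t0 = frames[0].timestamp_s
    z_of = lambda f: float(np.clip(z_lo + speed_nm_per_s * (f.timestamp_s - t0 - latency_s), z_lo, z_hi))
    peak = int(np.argmax(smoothed))
    best = z_of(frames[peak])
    at_boundary = peak in (0, len(frames) - 1)

    samples = [
        SharpnessSample(
            z_nm=z_of(f),
            score=float(s),
            frame_bytes=f.compressed_size_bytes,
            timestamp_s=f.timestamp_s,
        )
        for f, s in zip(frames, smoothed)
    ]
    scope.move_to(z_nm=best - approach_overshoot_nm)
    scope.move_to(z_nm=best)
    return FocusResult(best_z_nm=best, samples=samples, method="jpeg_fast", at_boundary=at_boundary)
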