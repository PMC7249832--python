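"""Optical calibration: resolution, distortion, shading, sampling, pixel size.

The resolution estimator is a knife-edge method: rows of an image containing
a near-vertical edge are aligned at their 50% crossings (a ~1 degree edge
tilt spreads the crossings over a pixel, which is what yields sub-pixel
sampling), pooled, and fit with a smoothing spline to give a low-noise edge
spread function.  Taking the square root converts intensity to amplitude
(appropriate for a coherently imaged edge) and differentiating yields the
point spread function, whose full width at half maximum is the resolution
figure.

Also here: the axisymmetric radial distortion fit from straight-edge scans,
the per-channel lens-shading (vignetting) gain table, a Nyquist-style
sampling adequacy check, and pixel-size calibration from a periodic target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.ndimage import map_coordinates, uniform_filter1d
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks

from .camera import to_gray

# -- containers ------------------------------------------------------------


@dataclass(frozen=True)
class EdgeSpreadProfile:
    """Pooled, spline-smoothed edge response, oriented dark -> bright."""

    positions_nm: np.ndarray
    values: np.ndarray  # normalized intensity, ~0 to ~1
    smoothing_parameter: float | None = None
    n_rows_used: int = 0
    pitch_nm: float = float("nan")


@dataclass(frozen=True)
class PsfEstimate:
    positions_nm: np.ndarray
    values: np.ndarray  # amplitude PSF, peak-normalized to 1
    fwhm_nm: float
    #: True when the width is within 2 pixel pitches of the sampling floor,
    #: where the estimate degrades and should not be trusted quantitatively
    resolution_limited: bool = False


@dataclass(frozen=True)
class DistortionFit:
    k: float  # radial coefficient, r' = r (1 + k r^2), r in half-diagonals
    max_fractional_displacement_pct: float
    rms_residual_px: float = float("nan")
    n_lines: int = 0


@dataclass(frozen=True)
class ShadingTable:
    """Coarse per-channel gain grid; bilinear interpolation to full size."""

    gains: np.ndarray  # (ny, nx, channels), min exactly 1
    interpolation: str = "bilinear"

    @property
    def grid_dims(self) -> tuple[int, int]:
        return self.gains.shape[1], self.gains.shape[0]


@dataclass(frozen=True)
class PixelCalibration:
    nm_per_px: float
    fov_um: tuple[float, float]


@dataclass(frozen=True)
class SamplingVerdict:
    effective_pitch_nm: float
    resolution_fwhm_nm: float
    adequately_sampled: bool

    @property
    def verdict(self) -> str:
        return "adequately sampled" if self.adequately_sampled else "undersampled"


class EdgeNotFoundError(ValueError):
    pass


#: Default roughness penalty for the edge-spread smoothing spline, with
#: positions in nanometres.  Calibrated so the spline's equivalent bandwidth
#: sits well below the optical blur (hundreds of nm) while suppressing
#: sub-pixel binning roughness; see the methods note.
DEFAULT_EDGE_SPLINE_LAM = 1e6


# -- knife-edge PSF pipeline ----------------------------------------------


def _row_edge_crossing(row: np.ndarray, rising: bool) -> float | None:
    """Sub-pixel column of the 50% crossing in one normalized row."""
    s = row - 0.5
    grad = np.diff(uniform_filter1d(row, size=5))
    if not rising:
        grad = -grad
    centre = int(np.argmax(grad))
    lo = max(centre - 4, 0)
    hi = min(centre + 5, len(row) - 1)
    for j in range(lo, hi):
        a, b = s[j], s[j + 1]
        crossing = (a <= 0 < b) if rising else (a >= 0 > b)
        if crossing and b != a:
            return j + (-a) / (b - a)
    return None


def detect_edge_points(image: np.ndarray) -> np.ndarray:
    """Per-row sub-pixel edge locations as (x_px, y_px) pairs."""
    gray = to_gray(image)
    lo, hi = np.percentile(gray, [2, 98])
    if hi <= lo:
        raise EdgeNotFoundError("edge not detected: image has no contrast")
    norm = (gray - lo) / (hi - lo)
    rising = norm[:, -norm.shape[1] // 4 :].mean() > norm[:, : norm.shape[1] // 4].mean()
    pts = []
    for i in range(norm.shape[0]):
        col = _row_edge_crossing(norm[i], rising)
        if col is not None:
            pts.append((col, float(i)))
    if len(pts) < 0.8 * norm.shape[0]:
        raise EdgeNotFoundError(
            f"edge not detected: monotone 50% crossing found in only "
            f"{len(pts)}/{norm.shape[0]} rows"
        )
    return np.array(pts)


def extract_edge_profile(
    image: np.ndarray,
    pitch_nm: float,
    smoothing: float | None = None,
    window_px: float = 30.0,
    oversample: int = 8,
) -> EdgeSpreadProfile:
    """Pooled sub-pixel edge spread function from a near-vertical edge.

    Each row's 50% crossing anchors that row to a common origin; the pooled
    (offset, intensity) samples are averaged in sub-pixel bins, fit with a
    smoothing spline and evaluated on a dense grid at ``pitch_nm /
    oversample`` spacing.  ``smoothing`` is the spline roughness penalty:
    None uses the calibrated default, ``"gcv"`` selects it by generalized
    cross-validation, a float is used as-is.
    """
    gray = to_gray(image)
    lo, hi = np.percentile(gray, [2, 98])
    if hi <= lo:
        raise EdgeNotFoundError("edge not detected: image has no contrast")
    norm = (gray - lo) / (hi - lo)
    points = detect_edge_points(image)  # (x_px, y_px)

    cols = np.arange(norm.shape[1], dtype=float)
    rising = norm[:, -norm.shape[1] // 4 :].mean() > norm[:, : norm.shape[1] // 4].mean()
    offsets, values = [], []
    for x_edge, y in points:
        row = norm[int(y)]
        rel = cols - x_edge
        keep = np.abs(rel) <= window_px
        offs = rel[keep]
        vals = row[keep]
        if not rising:  # flip so the profile always rises left to right
            offs = -offs
        offsets.append(offs)
        values.append(vals)
    x = np.concatenate(offsets) * pitch_nm
    y = np.concatenate(values)

    # pool into sub-pixel bins (averaging the many samples per bin beats the
    # noise down before the spline sees the data), then smooth
    bin_nm = pitch_nm / oversample
    edges = np.arange(x.min(), x.max() + bin_nm, bin_nm)
    idx = np.clip(np.digitize(x, edges) - 1, 0, len(edges) - 2)
    ysum = np.bincount(idx, weights=y, minlength=len(edges) - 1)
    ycnt = np.bincount(idx, minlength=len(edges) - 1)
    keep = ycnt > 0
    xu = (edges[:-1] + bin_nm / 2)[keep]
    yu = (ysum[keep]) / ycnt[keep]

    if smoothing is None:
        lam = DEFAULT_EDGE_SPLINE_LAM
    elif smoothing == "gcv":
        lam = None  # generalized cross-validation inside make_smoothing_spline
    else:
        lam = float(smoothing)
    spline = make_smoothing_spline(xu, yu, w=ycnt[keep].astype(float), lam=lam)
    grid = np.arange(xu[0], xu[-1], bin_nm)
    prof = spline(grid)

    # re-normalize on the plateaus so the profile spans [0, 1]
    tail = max(len(grid) // 8, 1)
    p_lo = float(np.median(prof[:tail]))
    p_hi = float(np.median(prof[-tail:]))
    if p_hi <= p_lo:
        raise EdgeNotFoundError("edge not detected: profile is not rising")
    prof = (prof - p_lo) / (p_hi - p_lo)

    return EdgeSpreadProfile(
        positions_nm=grid,
        values=prof,
        smoothing_parameter=lam,  # None when chosen by GCV internally
        n_rows_used=len(points),
        pitch_nm=pitch_nm,
    )


def _half_max_width(x: np.ndarray, y: np.ndarray) -> float:
    """FWHM by linear interpolation of the half-maximum crossings."""
    peak = int(np.argmax(y))
    half = y[peak] / 2.0

    def cross(idx_range) -> float | None:
        for j in idx_range:
            if y[j] < half:
                # interpolate between the first below-half sample and its
                # inner (towards-peak) neighbour
                inner = j + 1 if j < peak else j - 1
                y0, y1 = y[j], y[inner]
                if y1 == y0:
                    return float(x[j])
                t = (half - y0) / (y1 - y0)
                return float(x[j] + t * (x[inner] - x[j]))
        return None

    left = cross(range(peak - 1, -1, -1))
    right = cross(range(peak + 1, len(y)))
    if left is None or right is None:
        raise ValueError("profile too short to bracket both half-maximum crossings")
    return right - left


def psf_from_edge(profile: EdgeSpreadProfile, sqrt_first: bool = True) -> PsfEstimate:
    """Differentiate the edge response to obtain the PSF and its FWHM.

    With ``sqrt_first`` (the default) the square root of the normalized
    intensity is taken before differentiation, converting intensity to
    amplitude; disabling it treats the system as incoherent.
    """
    vals = np.clip(profile.values, 0.0, None)
    amp = np.sqrt(vals) if sqrt_first else vals
    psf = np.gradient(amp, profile.positions_nm)
    psf = np.clip(psf, 0.0, None)
    peak = psf.max()
    if peak <= 0:
        raise ValueError("degenerate edge profile: derivative is non-positive everywhere")
    psf = psf / peak
    fwhm = _half_max_width(profile.positions_nm, psf)
    limited = np.isfinite(profile.pitch_nm) and fwhm < 2 * profile.pitch_nm
    return PsfEstimate(
        positions_nm=profile.positions_nm,
        values=psf,
        fwhm_nm=fwhm,
        resolution_limited=bool(limited),
    )


# -- sampling adequacy -----------------------------------------------------


def sampling_check(
    pitch_nm: float, resolution_fwhm_nm: float, bayer_enabled: bool
) -> SamplingVerdict:
    """Is the pixel grid fine enough for the optical resolution?

    With a Bayer mosaic a 2x2 block of pixels forms one full-colour sample,
    so the effective sampling pitch doubles; sampling is adequate when the
    effective pitch is smaller than the resolution FWHM.
    """
    if pitch_nm <= 0 or resolution_fwhm_nm <= 0:
        raise ValueError("pitch and resolution must be positive")
    eff = 2.0 * pitch_nm if bayer_enabled else pitch_nm
    return SamplingVerdict(
        effective_pitch_nm=eff,
        resolution_fwhm_nm=resolution_fwhm_nm,
        adequately_sampled=eff < resolution_fwhm_nm,
    )


# -- radial distortion -----------------------------------------------------


def _line_residuals(points: np.ndarray) -> np.ndarray:
    """Perpendicular residuals of points from their total-least-squares line."""
    centred = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    normal = vt[-1]
    return centred @ normal


def _undistort_points(points: np.ndarray, centre: np.ndarray, half_diag: float, k: float):
    off = points - centre
    rp = np.hypot(off[:, 0], off[:, 1]) / half_diag
    r = rp.copy()
    for _ in range(4):
        r = r - (r * (1 + k * r * r) - rp) / (1 + 3 * k * r * r)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(rp > 0, r / rp, 1.0)
    return centre + off * s[:, None]


def estimate_distortion(
    edge_point_sets: list[np.ndarray],
    sensor_px: tuple[int, int],
    k_bounds: tuple[float, float] = (-0.2, 0.2),
) -> DistortionFit:
    """Fit the single-coefficient radial model to straight-edge scans.

    ``edge_point_sets`` holds, for each scan position of a straight edge
    across the field, the detected (x_px, y_px) edge points.  For a trial
    coefficient k every point set is undistorted and a total-least-squares
    line fit to it; k minimizes the pooled squared perpendicular residuals.
    The headline number is the worst-case displacement across the field,
    ``|k| * R`` at the corner (radius R = half-diagonal), expressed as a
    percentage of the field width.
    """
    if len(edge_point_sets) < 5:
        raise ValueError("need at least 5 scan positions spanning the field")
    w, h = sensor_px
    centre = np.array([(w - 1) / 2, (h - 1) / 2])
    half_diag = float(np.hypot(*centre))

    # degenerate geometry: radial distortion moves points along lines through
    # the centre, so lines through the centre carry no signal
    line_dists = [abs(_line_residuals_distance_from(pts, centre)) for pts in edge_point_sets]
    if max(line_dists) < 0.05 * half_diag:
        raise ValueError("degenerate geometry: all scanned lines pass through the image centre")

    def cost(k: float) -> float:
        total = 0.0
        for pts in edge_point_sets:
            und = _undistort_points(pts, centre, half_diag, k)
            r = _line_residuals(und)
            total += float(r @ r)
        return total

    res = minimize_scalar(cost, bounds=k_bounds, method="bounded", options={"xatol": 1e-7})
    k = float(res.x)

    n_pts = sum(len(p) for p in edge_point_sets)
    rms = float(np.sqrt(cost(k) / n_pts))
    max_disp_px = abs(k) * half_diag  # at the corner, r_norm = 1
    pct = 100.0 * max_disp_px / w
    return DistortionFit(
        k=k,
        max_fractional_displacement_pct=pct,
        rms_residual_px=rms,
        n_lines=len(edge_point_sets),
    )


def _line_residuals_distance_from(points: np.ndarray, origin: np.ndarray) -> float:
    """Distance of a point set's TLS line from a given origin point."""
    mean = points.mean(axis=0)
    centred = points - mean
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    normal = vt[-1]
    return float((origin - mean) @ normal)


def distortion_scan(scope, n_positions: int = 9, span_fraction: float = 0.8) -> DistortionFit:
    """End-to-end distortion measurement on a microscope with an edge target.

    Translates the stage so a straight edge crosses the field at
    ``n_positions`` lateral offsets spanning ``span_fraction`` of the field
    of view, detects the edge at each position and fits the radial model.
    """
    w, h = scope.camera.sensor_px
    fov_x = w * scope.optics.pixel_pitch_nm
    offsets = np.linspace(-span_fraction / 2, span_fraction / 2, n_positions) * fov_x
    start = scope.position_nm.copy()
    point_sets = []
    for dx in offsets:
        scope.move_to(x_nm=start[0] + dx)
        frame = scope.capture()
        point_sets.append(detect_edge_points(frame.pixels))
    scope.move_to(x_nm=start[0])
    return estimate_distortion(point_sets, scope.camera.sensor_px)


# -- lens shading ----------------------------------------------------------


def build_shading_table(
    flat_field_image: np.ndarray,
    grid_dims: tuple[int, int] = (32, 24),
    floor_fraction: float = 0.05,
) -> ShadingTable:
    """Coarse per-channel gain grid from a flat-field image.

    The image is divided into ``grid_dims`` (nx, ny) cells; each cell's gain
    is (brightest cell mean) / (cell mean), so the brightest region gets
    gain exactly 1 and vignetted corners get gains > 1.
    """
    img = np.asarray(flat_field_image, dtype=float)
    if img.ndim == 2:
        img = img[..., None]
    h, w, c = img.shape
    nx, ny = grid_dims
    ys = np.linspace(0, h, ny + 1).astype(int)
    xs = np.linspace(0, w, nx + 1).astype(int)
    means = np.empty((ny, nx, c))
    for i in range(ny):
        for j in range(nx):
            means[i, j] = img[ys[i] : ys[i + 1], xs[j] : xs[j + 1]].reshape(-1, c).mean(axis=0)
    top = means.reshape(-1, c).max(axis=0)
    if np.any(means < floor_fraction * top):
        raise ValueError(
            "insufficient illumination: some cells fall below "
            f"{floor_fraction:.0%} of the brightest cell"
        )
    gains = top / means
    gains = gains / gains.reshape(-1, c).min(axis=0)  # min gain exactly 1
    return ShadingTable(gains=gains)


def _interpolate_gains(table: ShadingTable, shape: tuple[int, int]) -> np.ndarray:
    """Bilinearly upsample the cell-centre gain grid to full resolution."""
    h, w = shape
    ny, nx, c = table.gains.shape
    # cell centres in pixel coordinates
    rows = (np.arange(h) + 0.5) * ny / h - 0.5
    cols = (np.arange(w) + 0.5) * nx / w - 0.5
    rr, cc = np.meshgrid(np.clip(rows, 0, ny - 1), np.clip(cols, 0, nx - 1), indexing="ij")
    out = np.empty((h, w, c))
    for ch in range(c):
        out[..., ch] = map_coordinates(table.gains[..., ch], [rr, cc], order=1, mode="nearest")
    return out


def apply_shading_correction(
    image: np.ndarray, table: ShadingTable, max_count: int = 255
) -> tuple[np.ndarray, int]:
    """Multiply an image by the interpolated gain field.

    Returns the corrected image (same dtype domain, clipped to ``max_count``)
    and the number of pixels that saturated during correction.
    """
    img = np.asarray(image, dtype=float)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[..., None]
    gains = _interpolate_gains(table, img.shape[:2])
    if gains.shape[2] != img.shape[2]:
        if img.shape[2] == 1:
            gains = gains.mean(axis=2, keepdims=True)
        elif gains.shape[2] == 1:
            gains = np.repeat(gains, img.shape[2], axis=2)
        else:
            raise ValueError(
                f"shading table has {gains.shape[2]} channels but image has {img.shape[2]}"
            )
    corrected = img * gains
    saturated = int(np.count_nonzero(corrected > max_count))
    corrected = np.clip(corrected, 0, max_count)
    if squeeze:
        corrected = corrected[..., 0]
    return corrected, saturated


# -- pixel-size calibration ------------------------------------------------


def _autocorr_period_px(signal: np.ndarray) -> float | None:
    """Dominant period of a 1-D signal via its autocorrelation peak."""
    x = signal - signal.mean()
    n = len(x)
    f = np.fft.rfft(x, n=2 * n)
    ac = np.fft.irfft(f * np.conj(f))[:n]
    if ac[0] <= 0:  # constant signal: no periodic structure
        return None
    ac /= ac[0]
    peaks, _ = find_peaks(ac, prominence=0.05)
    if len(peaks) == 0:
        return None
    p = int(peaks[0])  # first peak = the fundamental period
    if 1 <= p < n - 1:  # parabolic sub-sample refinement
        y0, y1, y2 = ac[p - 1], ac[p], ac[p + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            p = p + 0.5 * (y0 - y2) / denom
    return float(p)


def calibrate_pixel_size(
    image_of_grid: np.ndarray, known_pitch_um: float, sensor_px: tuple[int, int] | None = None
) -> PixelCalibration:
    """Distance-per-pixel from an image of a periodic grid of known pitch.

    The grid period in pixels is read off the first autocorrelation peak of
    the row- and column-averaged profiles; nm-per-pixel is then
    ``known_pitch / period`` and the field of view follows from the sensor
    dimensions.
    """
    gray = to_gray(image_of_grid)
    periods = []
    for profile in (gray.mean(axis=0), gray.mean(axis=1)):
        p = _autocorr_period_px(profile)
        if p is not None:
            periods.append(p)
    if not periods:
        raise ValueError("no periodic peak found in the image autocorrelation")
    period = float(np.mean(periods))
    nm_per_px = known_pitch_um * 1e3 / period
    if sensor_px is None:
        sensor_px = (gray.shape[1], gray.shape[0])
    fov = (sensor_px[0] * nm_per_px / 1e3, sensor_px[1] * nm_per_px / 1e3)
    return PixelCalibration(nm_per_px=nm_per_px, fov_um=fov)
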