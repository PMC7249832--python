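"""Virtual specimens.

A :class:`SpecimenField` is a flat virtual slide described by simple
primitives painted over a uniform background: absorbing disks (a stand-in for
a stained blood smear), a knife-edge target, a periodic grid target and flat
illumination fields.  Coordinates are sample-plane nanometres with the origin
at the centre of the slide, x to the right and y up.

The in-focus height across the slide is a plane,
``z_focus(x, y) = a*x + b*y + c``, so tilted specimens and focus gradients
can be emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class Primitive:
    """Base class: paints colour onto an RGB canvas at sample coordinates."""

    def paint(self, canvas: np.ndarray, u: np.ndarray, v: np.ndarray, aa_nm: float) -> None:
        raise NotImplementedError


def _rgb(colour, intensity) -> np.ndarray:
    if colour is None:
        return np.array([intensity, intensity, intensity], dtype=float)
    return np.asarray(colour, dtype=float) * intensity


def _blend(canvas: np.ndarray, alpha: np.ndarray, colour: np.ndarray) -> None:
    canvas *= (1 - alpha)[..., None]
    canvas += alpha[..., None] * colour


@dataclass
class Disk(Primitive):
    """An absorbing/coloured disk (e.g. a red blood cell).

    ``pallor`` lightens the central half-radius toward white, giving the
    annular look of an unstained-centre erythrocyte.
    """

    centre_um: tuple[float, float]
    radius_um: float
    intensity: float = 0.35
    colour: tuple[float, float, float] | None = None
    pallor: float = 0.0

    def paint(self, canvas, u, v, aa_nm):
        cx, cy = (c * 1e3 for c in self.centre_um)
        r_nm = self.radius_um * 1e3
        # restrict work to the disk's bounding box (u/v are near-regular grids)
        pad = r_nm + 5 * aa_nm
        cols = np.nonzero((u[0] >= cx - pad) & (u[0] <= cx + pad))[0]
        rows = np.nonzero((v[:, 0] >= cy - pad) & (v[:, 0] <= cy + pad))[0]
        if len(cols) == 0 or len(rows) == 0:
            return
        r0, r1 = rows[0], rows[-1] + 1
        c0, c1 = cols[0], cols[-1] + 1
        d = np.hypot(u[r0:r1, c0:c1] - cx, v[r0:r1, c0:c1] - cy)
        # anti-aliased edge over ~one pixel
        alpha = np.clip((r_nm - d) / max(aa_nm, 1e-9) + 0.5, 0.0, 1.0)
        rim = _rgb(self.colour, self.intensity)
        _blend(canvas[r0:r1, c0:c1], alpha, rim)
        if self.pallor > 0:
            inner = np.clip((0.5 * r_nm - d) / max(aa_nm, 1e-9) + 0.5, 0.0, 1.0)
            lightened = rim + (1.0 - rim) * self.pallor
            _blend(canvas[r0:r1, c0:c1], inner, lightened)


@dataclass
class EdgeTarget(Primitive):
    """A straight knife edge: dark on one side, bright on the other.

    ``angle_deg`` tilts the edge away from vertical; ``offset_um`` is the
    signed distance of the edge from the specimen origin along its normal.
    The bright side is the +normal side.
    """

    angle_deg: float = 0.0
    offset_um: float = 0.0
    bright: float = 1.0
    dark: float = 0.0

    def paint(self, canvas, u, v, aa_nm):
        theta = np.deg2rad(self.angle_deg)
        # edge direction is (sin, cos) ~ vertical; normal is (cos, -sin)
        s = u * np.cos(theta) - v * np.sin(theta) - self.offset_um * 1e3
        alpha = np.clip(s / max(aa_nm, 1e-9) + 0.5, 0.0, 1.0)
        value = self.dark + (self.bright - self.dark) * alpha
        canvas[:] = value[..., None]


@dataclass
class GridTarget(Primitive):
    """Periodic dark lines in both directions on a bright background."""

    pitch_um: float = 10.0
    line_width_um: float = 2.0
    bright: float = 0.95
    dark: float = 0.05

    def paint(self, canvas, u, v, aa_nm):
        pitch = self.pitch_um * 1e3
        half_w = self.line_width_um * 1e3 / 2
        du = np.abs((u + pitch / 2) % pitch - pitch / 2)
        dv = np.abs((v + pitch / 2) % pitch - pitch / 2)
        d = np.minimum(du, dv)  # distance to nearest grid line centreline
        alpha = np.clip((half_w - d) / max(aa_nm, 1e-9) + 0.5, 0.0, 1.0)
        value = self.bright + (self.dark - self.bright) * alpha
        canvas[:] = value[..., None]


@dataclass
class TextureField(Primitive):
    """Fine multiplicative stain-granularity texture (seeded value noise).

    Deterministic in absolute sample coordinates, so overlapping tiles see
    identical texture.  Features at ``scale_nm`` are partially resolved in
    focus and vanish under defocus blur — this is what makes compressed
    frame size (and any sharpness metric) peak at the focal plane.
    """

    amplitude: float = 0.08
    scale_nm: float = 700.0
    seed: int = 0

    def _hash(self, ix: np.ndarray, iy: np.ndarray) -> np.ndarray:
        s = np.sin(ix * 12.9898 + iy * 78.233 + self.seed * 0.618034) * 43758.5453
        return s - np.floor(s)

    def paint(self, canvas, u, v, aa_nm):
        gx, gy = u / self.scale_nm, v / self.scale_nm
        x0, y0 = np.floor(gx), np.floor(gy)
        fx, fy = gx - x0, gy - y0
        sx = fx * fx * (3 - 2 * fx)
        sy = fy * fy * (3 - 2 * fy)
        n = (
            self._hash(x0, y0) * (1 - sx) * (1 - sy)
            + self._hash(x0 + 1, y0) * sx * (1 - sy)
            + self._hash(x0, y0 + 1) * (1 - sx) * sy
            + self._hash(x0 + 1, y0 + 1) * sx * sy
        )
        canvas *= (1.0 + self.amplitude * (2 * n - 1))[..., None]
        np.clip(canvas, 0.0, 1.0, out=canvas)


@dataclass
class FlatTarget(Primitive):
    """Featureless uniform field, used for shading calibration."""

    intensity: float = 0.8
    colour: tuple[float, float, float] | None = None

    def paint(self, canvas, u, v, aa_nm):
        canvas[:] = _rgb(self.colour, self.intensity)


@dataclass
class SpecimenField:
    """A virtual slide: background, painted primitives and a focal plane."""

    extent_um: tuple[float, float] = (2000.0, 2000.0)
    primitives: list[Primitive] = field(default_factory=list)
    focal_surface: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (a, b, c_nm)
    background: float = 0.85

    @property
    def extent_nm(self) -> np.ndarray:
        return np.asarray(self.extent_um, dtype=float) * 1e3

    def focus_z_nm(self, x_nm: float, y_nm: float) -> float:
        """In-focus z at a lateral position: a*x + b*y + c."""
        a, b, c = self.focal_surface
        return a * x_nm + b * y_nm + c

    def evaluate_rgb(self, u: np.ndarray, v: np.ndarray, aa_nm: float) -> np.ndarray:
        """Ideal (pre-optics) RGB intensity in [0, 1] at sample coords (nm)."""
        canvas = np.full(u.shape + (3,), self.background, dtype=float)
        for prim in self.primitives:
            prim.paint(canvas, u, v, aa_nm)
        return np.clip(canvas, 0.0, 1.0)


# -- canned scenes ---------------------------------------------------------


def blood_smear_field(
    seed: int = 0,
    extent_um: tuple[float, float] = (2000.0, 2000.0),
    cell_density_per_mm2: float = 6000.0,
    radius_um: tuple[float, float] = (3.0, 4.5),
    focal_surface: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> SpecimenField:
    """Random field of reddish absorbing disks resembling a thin blood smear."""
    rng = np.random.default_rng(seed)
    area_mm2 = extent_um[0] * extent_um[1] / 1e6
    n = rng.poisson(cell_density_per_mm2 * area_mm2)
    prims: list[Primitive] = []
    for _ in range(n):
        cx = rng.uniform(-extent_um[0] / 2, extent_um[0] / 2)
        cy = rng.uniform(-extent_um[1] / 2, extent_um[1] / 2)
        r = rng.uniform(*radius_um)
        shade = rng.uniform(0.15, 0.4)
        prims.append(Disk((cx, cy), r, shade, colour=(1.0, 0.55, 0.55), pallor=0.5))
    prims.append(TextureField(amplitude=0.12, scale_nm=700.0, seed=seed))
    return SpecimenField(
        extent_um=extent_um, primitives=prims, focal_surface=focal_surface, background=0.85
    )


def knife_edge_field(
    angle_deg: float = 1.0,
    extent_um: tuple[float, float] = (2000.0, 2000.0),
    focal_surface: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> SpecimenField:
    """A single near-vertical knife edge through the slide centre."""
    return SpecimenField(
        extent_um=extent_um,
        primitives=[EdgeTarget(angle_deg=angle_deg)],
        focal_surface=focal_surface,
    )


def grid_field(
    pitch_um: float = 10.0,
    line_width_um: float = 2.0,
    extent_um: tuple[float, float] = (2000.0, 2000.0),
) -> SpecimenField:
    return SpecimenField(
        extent_um=extent_um,
        primitives=[GridTarget(pitch_um=pitch_um, line_width_um=line_width_um)],
    )


def flat_field(intensity: float = 0.8, extent_um=(2000.0, 2000.0)) -> SpecimenField:
    return SpecimenField(extent_um=extent_um, primitives=[FlatTarget(intensity=intensity)])
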