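"""Tile-scan and time-lapse planning and execution.

A grid scan visits ``nx x ny`` lateral sites (snake order by default, which
minimizes stage travel), runs the selected autofocus policy at each, then
captures a z-stack of ``nz`` images centred on the found focus.  Site
spacing is ``fov * (1 - overlap)`` so neighbouring tiles overlap for
stitching.  If autofocus fails at a site, the focus there is predicted from
a plane fit over previously focused sites — the thin flat-sample assumption
— and the site is flagged.

A time-lapse is a degenerate plan: one lateral site, many timed captures,
optionally re-focusing before each to cancel slow focus drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autofocus import FocusError, FocusResult, autofocus_sweep, jpeg_fast_autofocus
from .camera import Frame

AUTOFOCUS_POLICIES = ("none", "laplacian", "jpeg")


@dataclass(frozen=True)
class CaptureSite:
    grid_index: tuple[int, int]
    target_xy_nm: tuple[float, float]
    autofocus_policy: str = "laplacian"
    z_offsets_nm: tuple[float, ...] = (0.0,)
    capture_time_s: float | None = None  # set for time-lapse sites

    def __post_init__(self):
        if self.autofocus_policy not in AUTOFOCUS_POLICIES:
            raise ValueError(f"unknown autofocus policy {self.autofocus_policy!r}")
        if len(self.z_offsets_nm) == 0:
            raise ValueError("z_offsets_nm must be non-empty")
        if len(self.z_offsets_nm) % 2 == 1:
            offs = np.array(self.z_offsets_nm)
            if not np.allclose(offs + offs[::-1], 0.0):
                raise ValueError("odd-length z-stacks must be symmetric about 0")


@dataclass(frozen=True)
class ScanPlan:
    sites: list[CaptureSite]
    overlap_fraction: float = 0.0
    fov_um: tuple[float, float] = (0.0, 0.0)
    order: str = "snake"
    grid_shape: tuple[int, int] = (1, 1)

    @property
    def n_captures(self) -> int:
        return sum(len(s.z_offsets_nm) for s in self.sites)

    def total_travel_nm(self) -> float:
        """Summed |dx| + |dy| of the commanded site-to-site moves."""
        xy = np.array([s.target_xy_nm for s in self.sites])
        return float(np.sum(np.abs(np.diff(xy, axis=0))))


@dataclass(frozen=True)
class Tile:
    frame: Frame
    grid_index: tuple[int, int]
    nominal_xy_nm: tuple[float, float]
    z_offset_nm: float
    capture_z_nm: float
    site_index: int
    is_central: bool


@dataclass
class TileSet:
    tiles: list[Tile]
    plan: ScanPlan
    focus_results: list[FocusResult | None]
    failed_sites: list[int] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def central_tiles(self) -> list[Tile]:
        return [t for t in self.tiles if t.is_central]


def _z_offsets(nz: int, dz_nm: float) -> tuple[float, ...]:
    return tuple((np.arange(nz) - (nz - 1) / 2) * dz_nm)


def plan_grid_scan(
    nx: int,
    ny: int,
    nz: int = 1,
    dz_nm: float = 500.0,
    overlap_fraction: float = 0.2,
    fov_um: tuple[float, float] = (82.0, 61.6),
    order: str = "snake",
    autofocus_policy: str = "laplacian",
    centre_xy_nm: tuple[float, float] = (0.0, 0.0),
    travel_nm: tuple[float, float] | None = None,
) -> ScanPlan:
    """Lay out an ``nx x ny`` grid of capture sites with ``nz``-image stacks.

    Adjacent sites are spaced ``fov * (1 - overlap)`` on the traversed axis;
    the grid is centred on ``centre_xy_nm``.  With ``travel_nm`` given, sites
    outside the (centred) travel range raise an error listing the offenders.
    """
    if nx < 1 or ny < 1 or nz < 1:
        raise ValueError("nx, ny, nz must all be >= 1")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if order not in ("snake", "raster"):
        raise ValueError("order must be 'snake' or 'raster'")

    dx = fov_um[0] * 1e3 * (1 - overlap_fraction)
    dy = fov_um[1] * 1e3 * (1 - overlap_fraction)
    offsets = _z_offsets(nz, dz_nm)

    sites: list[CaptureSite] = []
    for j in range(ny):
        xs = range(nx)
        if order == "snake" and j % 2 == 1:
            xs = reversed(xs)
        for i in xs:
            x = centre_xy_nm[0] + (i - (nx - 1) / 2) * dx
            y = centre_xy_nm[1] + (j - (ny - 1) / 2) * dy
            sites.append(
                CaptureSite(
                    grid_index=(i, j),
                    target_xy_nm=(x, y),
                    autofocus_policy=autofocus_policy,
                    z_offsets_nm=offsets,
                )
            )

    if travel_nm is not None:
        bad = [
            s.grid_index
            for s in sites
            if abs(s.target_xy_nm[0]) > travel_nm[0] / 2
            or abs(s.target_xy_nm[1]) > travel_nm[1] / 2
        ]
        if bad:
            raise ValueError(f"scan plan exceeds stage travel at sites {bad}")

    return ScanPlan(
        sites=sites,
        overlap_fraction=overlap_fraction,
        fov_um=fov_um,
        order=order,
        grid_shape=(nx, ny),
    )


def plan_timelapse(
    n_frames: int,
    interval_s: float,
    autofocus_before_capture: bool = False,
    xy_nm: tuple[float, float] = (0.0, 0.0),
) -> ScanPlan:
    """A fixed-position, timed capture series (optionally refocused each frame)."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    policy = "laplacian" if autofocus_before_capture else "none"
    sites = [
        CaptureSite(
            grid_index=(0, t),
            target_xy_nm=xy_nm,
            autofocus_policy=policy,
            z_offsets_nm=(0.0,),
            capture_time_s=t * interval_s,
        )
        for t in range(n_frames)
    ]
    return ScanPlan(sites=sites, order="raster", grid_shape=(1, n_frames))


def _predict_focus(
    known: list[tuple[float, float, float]], xy: tuple[float, float], fallback: float
) -> float:
    """Plane-fit focus prediction from previously focused sites."""
    if len(known) >= 3:
        pts = np.array(known)
        A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
        coef, *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
        return float(coef[0] * xy[0] + coef[1] * xy[1] + coef[2])
    if known:
        return float(np.mean([k[2] for k in known]))
    return fallback


def execute_scan(
    plan: ScanPlan,
    scope,
    seed: int | None = None,
    af_range_nm: tuple[float, float] = (-10_000.0, 10_000.0),
    af_points: int = 11,
    af_speed_nm_per_s: float = 30_000.0,
) -> TileSet:
    """Run a scan plan on a microscope (virtual or real-device facade).

    Per site: move laterally, run the site's autofocus policy, then capture
    the z-stack bottom-to-top (constant approach direction).  The manifest
    records commanded/true positions, focus curves and timestamps.
    """
    if seed is not None:
        scope.seed = int(seed)

    tiles: list[Tile] = []
    focus_results: list[FocusResult | None] = []
    failed: list[int] = []
    focused_xyz: list[tuple[float, float, float]] = []
    site_records = []

    for s_idx, site in enumerate(plan.sites):
        if site.capture_time_s is not None and site.capture_time_s > scope.clock_s:
            scope.advance_clock(site.capture_time_s - scope.clock_s)
        scope.move_to(x_nm=site.target_xy_nm[0], y_nm=site.target_xy_nm[1])

        focus: FocusResult | None = None
        focus_failed = False
        if site.autofocus_policy == "none":
            best_z = float(scope.position_nm[2])
        else:
            try:
                if site.autofocus_policy == "laplacian":
                    focus = autofocus_sweep(scope, af_range_nm, af_points)
                else:
                    focus = jpeg_fast_autofocus(scope, af_range_nm, af_speed_nm_per_s)
                best_z = focus.best_z_nm
                focused_xyz.append((*site.target_xy_nm, best_z))
            except FocusError:
                focus_failed = True
                failed.append(s_idx)
                best_z = _predict_focus(
                    focused_xyz, site.target_xy_nm, float(scope.position_nm[2])
                )
        focus_results.append(focus)

        offsets = sorted(site.z_offsets_nm)
        central = min(site.z_offsets_nm, key=abs)
        scope.move_to(z_nm=best_z + offsets[0] - 2_000.0)  # approach stack from below
        for off in offsets:
            scope.move_to(z_nm=best_z + off)
            frame = scope.capture()
            tiles.append(
                Tile(
                    frame=frame,
                    grid_index=site.grid_index,
                    nominal_xy_nm=site.target_xy_nm,
                    z_offset_nm=off,
                    capture_z_nm=best_z + off,
                    site_index=s_idx,
                    is_central=(off == central),
                )
            )
        scope.move_to(z_nm=best_z)
        site_records.append(
            {
                "grid_index": list(site.grid_index),
                "target_xy_nm": list(site.target_xy_nm),
                "autofocus_policy": site.autofocus_policy,
                "best_z_nm": best_z,
                "focus_failed": focus_failed,
                "focus_curve": None
                if focus is None
                else [[smp.z_nm, smp.score] for smp in focus.samples],
                "timestamps_s": [
                    t.frame.timestamp_s for t in tiles if t.site_index == s_idx
                ],
            }
        )

    manifest = {
        "grid_shape": list(plan.grid_shape),
        "overlap_fraction": plan.overlap_fraction,
        "fov_um": list(plan.fov_um),
        "order": plan.order,
        "n_captures": len(tiles),
        "failed_sites": failed,
        "sites": site_records,
    }
    return TileSet(
        tiles=tiles,
        plan=plan,
        focus_results=focus_results,
        failed_sites=failed,
        manifest=manifest,
    )
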