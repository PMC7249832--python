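import numpy as np
import pytest

import simscope as ss

from conftest import make_scope


# -- planning ---------------------------------------------------------------


def test_grid_plan_counts_and_spacing():
    plan = ss.plan_grid_scan(3, 2, nz=1, overlap_fraction=0.2, fov_um=(20.0, 15.0))
    assert len(plan.sites) == 6
    assert plan.n_captures == 6
    xs = sorted({s.target_xy_nm[0] for s in plan.sites})
    assert np.allclose(np.diff(xs), 20e3 * 0.8)
    ys = sorted({s.target_xy_nm[1] for s in plan.sites})
    assert np.allclose(np.diff(ys), 15e3 * 0.8)
    # grid centred on the origin
    assert sum(s.target_xy_nm[0] for s in plan.sites) == pytest.approx(0.0, abs=1e-6)


def test_snake_order_shortens_travel():
    snake = ss.plan_grid_scan(5, 5, order="snake", fov_um=(20.0, 15.0))
    raster = ss.plan_grid_scan(5, 5, order="raster", fov_um=(20.0, 15.0))
    assert snake.total_travel_nm() < raster.total_travel_nm()


def test_zstack_offsets_symmetric():
    plan = ss.plan_grid_scan(1, 1, nz=5, dz_nm=400.0)
    offs = plan.sites[0].z_offsets_nm
    assert offs == (-800.0, -400.0, 0.0, 400.0, 800.0)


def test_travel_limit_lists_offenders():
    with pytest.raises(ValueError, match=r"exceeds stage travel at sites"):
        ss.plan_grid_scan(3, 1, fov_um=(9000.0, 15.0), travel_nm=(12e6, 12e6))


def test_plan_validation():
    with pytest.raises(ValueError):
        ss.plan_grid_scan(0, 1)
    with pytest.raises(ValueError):
        ss.plan_grid_scan(2, 2, overlap_fraction=1.0)
    with pytest.raises(ValueError):
        ss.plan_grid_scan(2, 2, order="spiral")
    with pytest.raises(ValueError):
        ss.CaptureSite((0, 0), (0, 0), autofocus_policy="magic")
    with pytest.raises(ValueError, match="symmetric"):
        ss.CaptureSite((0, 0), (0, 0), z_offsets_nm=(-100.0, 0.0, 300.0))


# -- execution --------------------------------------------------------------


def test_execute_scan_bookkeeping():
    scope = make_scope(camera=ss.CameraConfig(sensor_px=(120, 90)))
    plan = ss.plan_grid_scan(
        2, 2, nz=3, dz_nm=500.0, fov_um=(12.0, 9.0), autofocus_policy="none"
    )
    ts = ss.execute_scan(plan, scope)
    assert len(ts.tiles) == 12
    assert len(ts.central_tiles()) == 4
    assert all(t.z_offset_nm == 0.0 for t in ts.central_tiles())
    assert ts.manifest["n_captures"] == 12
    assert ts.manifest["grid_shape"] == [2, 2]
    assert len(ts.manifest["sites"]) == 4
    assert ts.failed_sites == []
    # z-stacks taken bottom-to-top
    for s in range(4):
        zs = [t.capture_z_nm for t in ts.tiles if t.site_index == s]
        assert zs == sorted(zs)


def test_scan_with_autofocus_tracks_tilted_specimen():
    spec = ss.blood_smear_field(
        seed=3, extent_um=(300, 300), focal_surface=(0.05, -0.03, 200.0)
    )
    scope = make_scope(specimen=spec, camera=ss.CameraConfig(sensor_px=(400, 300)), seed=6)
    plan = ss.plan_grid_scan(
        2, 2, nz=1, overlap_fraction=0.2, fov_um=(40.0, 30.0), autofocus_policy="laplacian"
    )
    ts = ss.execute_scan(plan, scope, af_range_nm=(-5000, 5000), af_points=15)
    assert ts.failed_sites == []
    tol = scope.optics.depth_of_focus_nm()  # 10% blur growth
    for t in ts.central_tiles():
        x, y, z = t.frame.true_position_nm
        defocus = abs(z - spec.focus_z_nm(x, y))
        assert defocus <= tol


def test_focus_failure_falls_back_to_plane_fit():
    # tilted focal plane; one site over a featureless void where the jpeg
    # metric is flat -> FocusError -> plane-fit prediction from other sites
    spec = ss.blood_smear_field(seed=3, extent_um=(400, 400), focal_surface=(0.02, 0.01, 0.0))

    # carve a featureless rectangle over one site by painting background on it
    import dataclasses

    @dataclasses.dataclass
    class Patch:
        x0: float
        x1: float
        y0: float
        y1: float

        def paint(self, canvas, u, v, aa_nm):
            m = (u >= self.x0) & (u <= self.x1) & (v >= self.y0) & (v <= self.y1)
            canvas[m] = 0.85

    # site (1, 1) sits at (10, 7.5) um with a 20 x 15 um field of view
    spec.primitives.append(Patch(-2e3, 22e3, -2e3, 17e3))
    scope = make_scope(specimen=spec, camera=ss.CameraConfig(sensor_px=(200, 150)), seed=6)
    plan = ss.plan_grid_scan(
        2, 2, nz=1, overlap_fraction=0.0, fov_um=(20.0, 15.0), autofocus_policy="jpeg"
    )
    ts = ss.execute_scan(plan, scope, af_range_nm=(-4000, 4000), af_speed_nm_per_s=20_000)
    assert len(ts.failed_sites) == 1
    failed = ts.failed_sites[0]
    rec = ts.manifest["sites"][failed]
    assert rec["focus_failed"]
    # plane-fit fallback keeps the failed site near the true focal plane
    x, y = rec["target_xy_nm"]
    assert abs(rec["best_z_nm"] - spec.focus_z_nm(x, y)) < 1000.0


def test_timelapse_plan_and_drift_compensation():
    plan = ss.plan_timelapse(n_frames=4, interval_s=60.0)
    assert len(plan.sites) == 4
    assert plan.sites[2].capture_time_s == 120.0
    with pytest.raises(ValueError):
        ss.plan_timelapse(0, 10.0)
    with pytest.raises(ValueError):
        ss.plan_timelapse(3, -1.0)

    spec = ss.blood_smear_field(seed=3, extent_um=(300, 300))
    drift = [0, 0, 3600]  # 1 nm/s of z drift
    cam = ss.CameraConfig(sensor_px=(300, 225))

    def run(autofocus):
        stage = ss.StageState(step_size_nm=[70, 70, 50], drift_rate_nm_per_hour=drift)
        scope = make_scope(specimen=spec, camera=cam, stage=stage, seed=5)
        p = ss.plan_timelapse(6, 600.0, autofocus_before_capture=autofocus)
        ts = ss.execute_scan(p, scope, af_range_nm=(-5000, 5000), af_points=15)
        errs = []
        for t in ts.tiles:
            x, y, z = t.frame.true_position_nm
            errs.append(abs(z - spec.focus_z_nm(x, y)))
        return np.array(errs)

    free = run(False)
    held = run(True)
    sweep_step = 10_000 / 14
    assert held.max() <= sweep_step  # autofocus bounds the focus error
    assert free[-1] > 4 * held.max()  # without it, drift runs away
    assert np.all(np.diff(free) > 0)  # and it grows monotonically
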