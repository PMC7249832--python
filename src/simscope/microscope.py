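"""The virtual microscope: stage + optics + specimen + camera + clock.

``VirtualMicroscope`` is the stateful facade the acquisition algorithms
(autofocus, scanning, time-lapse) drive.  It keeps a wall clock: moves take
``distance / move_speed`` plus a settle time, captures take one exposure, and
stage drift accumulates with elapsed time whether or not moves occur.  Every
captured frame draws its noise from a generator seeded by ``(seed, frame
counter)`` so whole acquisition runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .camera import CameraConfig, Frame
from .optics import OpticsConfig
from .render import render_frame
from .specimen import SpecimenField
from .stage import StageState, apply_drift, move_to


class VirtualMicroscope:
    def __init__(
        self,
        specimen: SpecimenField,
        optics: OpticsConfig | None = None,
        camera: CameraConfig | None = None,
        stage: StageState | None = None,
        seed: int = 0,
        move_speed_nm_per_s: float = 2e5,
        settle_time_s: float = 0.2,
    ):
        self.specimen = specimen
        self.optics = optics or OpticsConfig()
        self.camera = camera or CameraConfig()
        self.stage = stage or StageState()
        self.seed = int(seed)
        self.move_speed_nm_per_s = move_speed_nm_per_s
        self.settle_time_s = settle_time_s
        self.clock_s = 0.0
        self.frame_counter = 0

    # -- time -------------------------------------------------------------

    def advance_clock(self, dt_s: float) -> None:
        """Let ``dt_s`` pass: the clock ticks and drift accumulates."""
        if dt_s < 0:
            raise ValueError("time cannot run backwards")
        self.clock_s += dt_s
        self.stage = apply_drift(self.stage, dt_s / 3600.0)

    # -- motion -----------------------------------------------------------

    @property
    def position_nm(self) -> np.ndarray:
        return self.stage.position_nm

    def move_to(self, x_nm=None, y_nm=None, z_nm=None, settle: bool = True) -> None:
        """Move to an absolute position; unspecified axes stay put."""
        cur = self.stage.position_nm
        target = np.array(
            [
                cur[0] if x_nm is None else x_nm,
                cur[1] if y_nm is None else y_nm,
                cur[2] if z_nm is None else z_nm,
            ],
            dtype=float,
        )
        dist = float(np.max(np.abs(target - cur)))
        self.stage = move_to(self.stage, target)
        dt = dist / self.move_speed_nm_per_s + (self.settle_time_s if settle else 0.0)
        self.advance_clock(dt)

    def move_z_backlash_corrected(self, z_nm: float, overshoot_nm: float = 5000.0) -> None:
        """Approach a z target always from below, cancelling backlash."""
        self.move_to(z_nm=z_nm - overshoot_nm)
        self.move_to(z_nm=z_nm)

    # -- imaging ----------------------------------------------------------

    def capture(self) -> Frame:
        """Capture one frame at the current position."""
        frame = render_frame(
            self.stage,
            self.optics,
            self.specimen,
            self.camera,
            seed=[self.seed, self.frame_counter],
            timestamp_s=self.clock_s,
        )
        self.frame_counter += 1
        self.advance_clock(self.camera.exposure_s)
        return frame

    def stream_z(self, z_start_nm: float, z_end_nm: float, speed_nm_per_s: float) -> list[Frame]:
        """Capture frames continuously while the stage sweeps z at constant speed.

        The stage is assumed to already sit at ``z_start_nm``; frames arrive
        at the camera frame rate and are timestamped, and the stage ends at
        ``z_end_nm``.  Used by the compressed-frame-size autofocus.
        """
        if speed_nm_per_s <= 0:
            raise ValueError("speed must be positive")
        span = z_end_nm - z_start_nm
        duration = abs(span) / speed_nm_per_s
        dt = 1.0 / self.camera.frame_rate_hz
        n_frames = max(int(np.floor(duration / dt)) + 1, 1)
        direction = np.sign(span)
        frames: list[Frame] = []
        for i in range(n_frames):
            t = i * dt
            z = z_start_nm + direction * speed_nm_per_s * t
            self.stage = move_to(
                self.stage, [self.stage.position_nm[0], self.stage.position_nm[1], z]
            )
            frames.append(self.capture())
            # capture() advanced the clock by one exposure; pad to the frame interval
            self.advance_clock(max(0.0, dt - self.camera.exposure_s))
        self.move_to(z_nm=z_end_nm, settle=False)
        return frames

    # -- ground truth (for tests and reports) -----------------------------

    def true_focus_z_nm(self, x_nm: float | None = None, y_nm: float | None = None) -> float:
        """In-focus z of the focal surface at a lateral position (simulator truth)."""
        pos = self.stage.physical_position_nm
        x = pos[0] if x_nm is None else x_nm
        y = pos[1] if y_nm is None else y_nm
        return self.specimen.focus_z_nm(x, y) - float(self.stage.drift_offset_nm[2])
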