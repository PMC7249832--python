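"""Three-axis motorized-stage model.

The stage is driven in discrete actuator steps (defaults: 70 nm in x and y,
50 nm in z) over a 12 x 12 x 4 mm travel range.  Moves are commanded in
nanometres relative to the centre of travel and quantized to whole steps with
round-half-to-even.  Two mechanical imperfections are modelled:

* **backlash** — a slot of ``backlash_steps`` steps of lost motion per axis:
  moving in the positive direction engages the carriage exactly at the
  commanded position, while a reversal leaves the physical position lagging by
  up to ``backlash_steps`` steps until the slack is taken up again.
* **drift** — a slow, move-independent offset of the physical position that
  accumulates at ``drift_rate_nm_per_hour`` (flexure stages are known to drift
  by tens of microns over several days).

``StageState`` is immutable; every operation returns a new state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

AXES = ("x", "y", "z")

DEFAULT_STEP_NM = (70.0, 70.0, 50.0)
DEFAULT_TRAVEL_NM = (12e6, 12e6, 4e6)


def _vec3(value, dtype=float) -> np.ndarray:
    arr = np.asarray(value, dtype=dtype)
    if arr.shape == ():
        arr = np.full(3, arr)
    if arr.shape != (3,):
        raise ValueError(f"expected scalar or 3-vector (x, y, z), got shape {arr.shape}")
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True)
class StageState:
    """Commanded and physical stage position with actuator parameters.

    ``position_steps`` (commanded) and ``physical_steps`` are whole steps
    relative to the centre of travel (the coordinate origin), so positions
    are always step-quantized and confined to ``+-travel/2`` per axis.
    """

    step_size_nm: np.ndarray = field(default_factory=lambda: _vec3(DEFAULT_STEP_NM))
    travel_nm: np.ndarray = field(default_factory=lambda: _vec3(DEFAULT_TRAVEL_NM))
    backlash_steps: np.ndarray = field(default_factory=lambda: _vec3(0, dtype=np.int64))
    drift_rate_nm_per_hour: np.ndarray = field(default_factory=lambda: _vec3(0.0))
    position_steps: np.ndarray = None  # type: ignore[assignment]
    physical_steps: np.ndarray = None  # type: ignore[assignment]
    last_move_direction: np.ndarray = field(default_factory=lambda: _vec3(0, dtype=np.int64))
    drift_offset_nm: np.ndarray = field(default_factory=lambda: _vec3(0.0))
    clamped: bool = False

    def __post_init__(self):
        object.__setattr__(self, "step_size_nm", _vec3(self.step_size_nm))
        object.__setattr__(self, "travel_nm", _vec3(self.travel_nm))
        object.__setattr__(self, "backlash_steps", _vec3(self.backlash_steps, np.int64))
        object.__setattr__(self, "drift_rate_nm_per_hour", _vec3(self.drift_rate_nm_per_hour))
        if np.any(self.backlash_steps < 0):
            raise ValueError("backlash_steps must be non-negative")
        if self.position_steps is None:
            object.__setattr__(self, "position_steps", _vec3(0, dtype=np.int64))
        else:
            object.__setattr__(self, "position_steps", _vec3(self.position_steps, np.int64))
        if self.physical_steps is None:
            object.__setattr__(self, "physical_steps", self.position_steps)
        else:
            object.__setattr__(self, "physical_steps", _vec3(self.physical_steps, np.int64))
        object.__setattr__(self, "last_move_direction", _vec3(self.last_move_direction, np.int64))
        object.__setattr__(self, "drift_offset_nm", _vec3(self.drift_offset_nm))
        if np.any(np.abs(self.position_steps) > self.max_steps):
            raise ValueError("position outside travel range")

    # -- coordinates ------------------------------------------------------

    @property
    def position_nm(self) -> np.ndarray:
        """Commanded position, nm relative to the centre of travel."""
        return self.position_steps * self.step_size_nm

    @property
    def physical_position_nm(self) -> np.ndarray:
        """True (carriage) position including backlash lag and drift."""
        return self.physical_steps * self.step_size_nm + self.drift_offset_nm

    @property
    def max_steps(self) -> np.ndarray:
        """Steps from the origin to either end of travel."""
        return np.floor(self.travel_nm / 2 / self.step_size_nm).astype(np.int64)


def move_to(stage: StageState, target_nm) -> StageState:
    """Move the stage to an absolute centred-coordinate target (nm per axis).

    The target is quantized to whole steps (round half to even) and clamped to
    the travel range; clamping is reported via the returned state's
    ``clamped`` flag.  Backlash is applied through the slot model: the
    physical position is confined to ``[commanded, commanded + backlash]``
    steps and is only pushed by the wall the motion engages.
    """
    target_nm = _vec3(target_nm)
    raw_steps = target_nm / stage.step_size_nm
    steps = np.rint(raw_steps).astype(np.int64)  # numpy rounds half to even
    clamped_steps = np.clip(steps, -stage.max_steps, stage.max_steps)
    was_clamped = bool(np.any(clamped_steps != steps))

    delta = clamped_steps - stage.position_steps
    direction = np.sign(delta).astype(np.int64)
    # carriage sits in a slot [commanded, commanded + backlash]
    physical = np.clip(
        stage.physical_steps, clamped_steps, clamped_steps + stage.backlash_steps
    )
    new_dir = np.where(direction != 0, direction, stage.last_move_direction)
    return replace(
        stage,
        position_steps=clamped_steps,
        physical_steps=physical,
        last_move_direction=new_dir,
        clamped=was_clamped,
    )


def move_by(stage: StageState, delta_nm) -> StageState:
    """Relative move; convenience wrapper over :func:`move_to`."""
    return move_to(stage, stage.position_nm + _vec3(delta_nm))


def apply_drift(stage: StageState, elapsed_hours: float) -> StageState:
    """Accumulate mechanical drift over ``elapsed_hours``.

    Drift offsets the physical position only, independently of any moves
    commanded in between; successive calls are additive.
    """
    if elapsed_hours < 0:
        raise ValueError("elapsed_hours must be non-negative")
    offset = stage.drift_offset_nm + stage.drift_rate_nm_per_hour * elapsed_hours
    return replace(stage, drift_offset_nm=offset)
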