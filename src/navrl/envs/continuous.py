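"""Continuous 2D arena with cardinal or differential-drive kinematics.

The arena is an obstacle-free rectangle.  In ``cardinal`` mode the agent
translates by a fixed step in one of the four compass directions; in
``differential`` mode it is a two-wheeled robot whose action is the pair of
wheel speeds ``(v_l, v_r)`` in units/s, integrated over ``dt`` with linear
velocity ``v = (v_l + v_r) / 2`` and angular velocity ``w = (v_r - v_l) / b``
for wheel base ``b``.  Positions are clipped to the arena bounds.  Entering a
reward disc ends the trial with its value; optionally, touching a wall ends
the trial too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Continuous2DSpec:
    """Arena geometry, kinematics mode and reward layout."""

    xmin: float = 0.0
    xmax: float = 1.0
    ymin: float = 0.0
    ymax: float = 1.0
    mode: str = "cardinal"  # "cardinal" | "differential"
    step_size: float = 0.1  # meters per cardinal move
    wheel_base: float = 0.1  # meters (differential mode)
    dt: float = 0.1  # seconds per step
    max_wheel_speed: float = 1.0  # units/s, wheel speeds clipped to [-max, max]
    #: (x, y, radius, value) per reward location
    reward_locations: list[tuple[float, float, float, float]] = field(default_factory=list)
    terminate_on_wall: bool = False

    def __post_init__(self):
        if self.xmax <= self.xmin or self.ymax <= self.ymin:
            raise ValueError("arena bounds are degenerate")
        if self.mode not in ("cardinal", "differential"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(r <= 0 for _, _, r, _ in self.reward_locations):
            raise ValueError("reward radii must be positive")


#: pose is (x, y, heading) with heading in radians, CCW from +x.
CARDINAL_DELTAS = ((1.0, 0.0), (0.0, 1.0), (-1.0, 0.0), (0.0, -1.0))  # E N W S


def continuous2d_step(
    spec: Continuous2DSpec,
    pose: tuple[float, float, float],
    action,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[float, float, float], float, bool]:
    """Advance the pose by one action; returns ``(pose, reward, terminal)``.

    Cardinal actions are integers 0-3 (east, north, west, south).  Differential
    actions are ``(v_l, v_r)`` wheel-speed pairs; the heading is advanced by
    ``w * dt`` and the position by ``v * dt`` along the pre-step heading, which
    makes a pure spin (``v_l = -v_r``) leave the position exactly unchanged.
    """
    x, y, theta = pose
    if spec.mode == "cardinal":
        a = int(action)
        if not (0 <= a < 4):
            raise ValueError(f"cardinal action {action!r} out of range")
        dx, dy = CARDINAL_DELTAS[a]
        nx, ny = x + dx * spec.step_size, y + dy * spec.step_size
        ntheta = theta
    else:
        try:
            v_l, v_r = float(action[0]), float(action[1])
        except (TypeError, IndexError) as err:
            raise ValueError(
                f"differential mode expects (v_l, v_r), got {action!r}") from err
        cap = spec.max_wheel_speed
        v_l, v_r = np.clip(v_l, -cap, cap), np.clip(v_r, -cap, cap)
        v = 0.5 * (v_l + v_r)
        w = (v_r - v_l) / spec.wheel_base
        nx = x + v * np.cos(theta) * spec.dt
        ny = y + v * np.sin(theta) * spec.dt
        ntheta = (theta + w * spec.dt) % (2.0 * np.pi)
    hit_wall = nx < spec.xmin or nx > spec.xmax or ny < spec.ymin or ny > spec.ymax
    nx = float(np.clip(nx, spec.xmin, spec.xmax))
    ny = float(np.clip(ny, spec.ymin, spec.ymax))
    reward, terminal = 0.0, False
    for rx, ry, radius, value in spec.reward_locations:
        if (nx - rx) ** 2 + (ny - ry) ** 2 <= radius**2:
            reward, terminal = value, True
            break
    if spec.terminate_on_wall and hit_wall:
        terminal = True
    return (nx, ny, float(ntheta)), reward, terminal


class Continuous2DEnv:
    """Trial-based wrapper: random start pose, step via :func:`continuous2d_step`."""

    def __init__(self, spec: Continuous2DSpec):
        self.spec = spec
        self.state: tuple[float, float, float] | None = None

    @property
    def n_actions(self) -> int:
        return 4 if self.spec.mode == "cardinal" else 2

    def reset(self, rng: np.random.Generator):
        s = self.spec
        while True:
            x = rng.uniform(s.xmin, s.xmax)
            y = rng.uniform(s.ymin, s.ymax)
            if not any((x - rx) ** 2 + (y - ry) ** 2 <= r**2
                       for rx, ry, r, _ in s.reward_locations):
                break
        theta = rng.uniform(0.0, 2.0 * np.pi)
        self.state = (x, y, theta)
        return self.state

    def step(self, action, rng: np.random.Generator):
        self.state, reward, terminal = continuous2d_step(self.spec, self.state, action, rng)
        return self.state, reward, terminal
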