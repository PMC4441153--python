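"""Trajectory generation: random foraging with momentum, and noisy
waypoint following, both at constant speed.

The agent moves in discrete time steps of ``dt`` seconds, covering exactly
``speed * dt`` cm per step (the virtual rat never slows down or stops).  Its
heading is the direction of motion — the panoramic camera looks where the
agent moves.  A wall margin keeps every sample a fixed distance away from
all walls, emulating the extent of a physical body.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .environment import MazeSpec, contains

__all__ = ["Trajectory", "BehaviorSpec", "forage", "follow_waypoints", "truncate"]

DEFAULT_DT = 0.05  # s per step: 20 samples/s, 1 cm per step at 20 cm/s
DEFAULT_SPEED = 20.0  # cm/s


@dataclass
class Trajectory:
    positions: np.ndarray  # (T, 2) cm
    headings: np.ndarray  # (T,) degrees CCW from east (direction of motion)
    dt: float
    speed: float

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.positions)) * self.dt

    @property
    def duration(self) -> float:
        return len(self.positions) * self.dt

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t", "x", "y", "heading"])
            for t, (x, y), h in zip(self.times, self.positions, self.headings):
                w.writerow([f"{t:.6f}", f"{x:.9f}", f"{y:.9f}", f"{h:.9f}"])

    @classmethod
    def from_csv(cls, path, dt: float | None = None, speed: float | None = None):
        rows = []
        with open(path) as fh:
            for rec in csv.DictReader(fh):
                rows.append((float(rec["t"]), float(rec["x"]), float(rec["y"]),
                             float(rec["heading"])))
        arr = np.array(rows)
        if dt is None:
            dt = float(arr[1, 0] - arr[0, 0]) if len(arr) > 1 else DEFAULT_DT
        pos = arr[:, 1:3]
        if speed is None:
            step = float(np.hypot(*(pos[1] - pos[0]))) if len(arr) > 1 else DEFAULT_SPEED * dt
            speed = step / dt
        return cls(pos, arr[:, 3], dt, speed)


@dataclass
class BehaviorSpec:
    """Movement-policy parameters.

    ``momentum`` blends the previous heading with each newly drawn direction
    (1 = never turn); ``turn_limit`` bounds how far (degrees) a new direction
    may deviate from the current heading — by default the half-angle of the
    agent's 320-degree field of view.  The default momentum keeps rotation
    fast relative to translation, the regime in which slowness extracts
    position rather than head direction.
    """

    mode: str = "forage"
    momentum: float = 0.2
    turn_limit: float = 160.0
    waypoints: list[tuple[float, float]] = field(default_factory=list)
    waypoint_noise: float = 3.0
    wall_margin: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.momentum <= 1.0:
            raise ValueError("momentum must lie in [0, 1]")
        if self.wall_margin < 0:
            raise ValueError("wall_margin must be non-negative")


def _wrap(angle: float) -> float:
    return (angle + 180.0) % 360.0 - 180.0


def _random_interior_point(maze, margin, rng):
    x0, y0, x1, y1 = maze.floor_bounds
    for _ in range(10_000):
        p = (rng.uniform(x0, x1), rng.uniform(y0, y1))
        if contains(maze, p, margin):
            return p
    raise ValueError("arena too small to admit wall_margin")


def _step_with_avoidance(maze, p, heading_try, step_len, margin, rng, fallback_aim):
    """Return (new_position, heading) keeping the step length exact.

    If the tried heading violates the wall margin the step is re-aimed
    toward the arena interior (jittered directions around ``fallback_aim``).
    """
    h = heading_try
    for attempt in range(60):
        q = (p[0] + step_len * math.cos(math.radians(h)),
             p[1] + step_len * math.sin(math.radians(h)))
        if contains(maze, q, margin):
            return q, h
        aim = fallback_aim(p)
        jitter = rng.uniform(-75.0, 75.0) if attempt < 55 else 0.0
        h = aim + jitter
    raise ValueError("arena too small to admit wall_margin")


def forage(
    maze: MazeSpec,
    behavior: BehaviorSpec,
    duration: float,
    dt: float = DEFAULT_DT,
    speed: float = DEFAULT_SPEED,
    start: tuple[float, float] | None = None,
    start_heading: float | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Random exploration: each step draws a direction uniformly within
    ±turn_limit of the current heading, blends it with the momentum term,
    and moves exactly ``speed * dt`` cm."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if behavior.mode != "forage":
        raise ValueError("behavior.mode must be 'forage'")
    rng = rng if rng is not None else np.random.default_rng(behavior.seed)
    n = int(round(duration / dt))
    step_len = speed * dt
    cx, cy = maze.region.centroid.x, maze.region.centroid.y

    def aim_center(p):
        return math.degrees(math.atan2(cy - p[1], cx - p[0]))

    p = start if start is not None else _random_interior_point(maze, behavior.wall_margin, rng)
    if not contains(maze, p, behavior.wall_margin):
        raise ValueError("start position violates wall margin")
    h = start_heading if start_heading is not None else rng.uniform(0.0, 360.0)

    positions = np.empty((n, 2))
    headings = np.empty(n)
    for i in range(n):
        delta = rng.uniform(-behavior.turn_limit, behavior.turn_limit)
        h_try = h + (1.0 - behavior.momentum) * delta
        q, h = _step_with_avoidance(
            maze, p, h_try, step_len, behavior.wall_margin, rng, aim_center
        )
        positions[i] = p
        headings[i] = h % 360.0
        p = q
    return Trajectory(positions, headings, dt, speed)


def follow_waypoints(
    maze: MazeSpec,
    behavior: BehaviorSpec,
    duration: float,
    dt: float = DEFAULT_DT,
    speed: float = DEFAULT_SPEED,
    rng: np.random.Generator | None = None,
    reverse: bool = False,
) -> Trajectory:
    """Cycle through the waypoint list with per-step lateral noise of scale
    ``waypoint_noise`` cm, so no two laps follow the exact same path."""
    if behavior.mode != "waypoints":
        raise ValueError("behavior.mode must be 'waypoints'")
    wps = list(behavior.waypoints)
    if not wps:
        raise ValueError("waypoint list is empty")
    if reverse:
        wps = wps[::-1]
    for wp in wps:
        if not contains(maze, wp, behavior.wall_margin):
            raise ValueError(f"waypoint {wp} outside arena (margin applied)")
    rng = rng if rng is not None else np.random.default_rng(behavior.seed)
    n = int(round(duration / dt))
    step_len = speed * dt
    capture = max(2.0 * step_len, 3.0)
    noise_gain = behavior.waypoint_noise / 10.0

    p = wps[0]
    target = 1 % len(wps)
    positions = np.empty((n, 2))
    headings = np.empty(n)

    def aim_target(pp):
        wp = wps[target]
        return math.degrees(math.atan2(wp[1] - pp[1], wp[0] - pp[0]))

    for i in range(n):
        wp = wps[target]
        dx, dy = wp[0] - p[0], wp[1] - p[1]
        if math.hypot(dx, dy) < capture:
            target = (target + 1) % len(wps)
            wp = wps[target]
            dx, dy = wp[0] - p[0], wp[1] - p[1]
        desired = math.atan2(dy, dx)
        ux, uy = math.cos(desired), math.sin(desired)
        eta = rng.normal() * noise_gain
        vx, vy = ux - eta * uy, uy + eta * ux  # lateral perturbation
        h_try = math.degrees(math.atan2(vy, vx))
        q, h = _step_with_avoidance(
            maze, p, h_try, step_len, behavior.wall_margin, rng, aim_target
        )
        positions[i] = p
        headings[i] = h % 360.0
        p = q
    return Trajectory(positions, headings, dt, speed)


def truncate(traj: Trajectory, cutoff_time: float) -> Trajectory:
    """Prefix of a trajectory up to ``cutoff_time`` seconds."""
    if cutoff_time > traj.duration + 1e-9:
        raise ValueError("cutoff beyond trajectory duration")
    n = int(round(cutoff_time / traj.dt))
    return Trajectory(traj.positions[:n].copy(), traj.headings[:n].copy(),
                      traj.dt, traj.speed)
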