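"""Spatial activity maps from a trained network.

Two sampling routes are provided, matching how simulated place fields are
inspected:

* dense grid sampling: the arena is scanned on a regular grid with a fixed
  head direction (8-point compass), the network is evaluated at every
  reachable grid point, and each output cell yields one map per direction
  (plus their pixelwise average);
* trajectory sampling with spike emulation: activities along a behaviour
  trajectory are rectified, normalised by the cell's trajectory-wide peak
  and used as per-step firing probabilities; emitted spikes are accumulated
  in spatial bins, divided by occupancy time and Gaussian-smoothed over the
  visited area — the standard experimental ratemap pipeline.

Pixels outside the arena (or never visited) are flagged invalid and carry
NaN, never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .environment import MazeSpec, contains
from .hierarchy import NetworkModel, forward_stream
from .motion import Trajectory, truncate
from .renderer import CameraModel, render_poses

__all__ = [
    "RateMap",
    "SpikeRecord",
    "COMPASS",
    "sample_fixed_direction",
    "sample_direction_set",
    "average_map",
    "emulate_spikes",
    "bin_and_smooth",
    "occupancy_limited_map",
    "trajectory_ratemaps",
]

#: the eight fixed sampling head directions, degrees CCW from east
COMPASS = {
    "E": 0.0, "NE": 45.0, "N": 90.0, "NW": 135.0,
    "W": 180.0, "SW": 225.0, "S": 270.0, "SE": 315.0,
}


@dataclass
class RateMap:
    """Per-cell scalar activity on a regular spatial grid.

    ``values[iy, ix]`` covers the square centred at
    (x0 + (ix + 0.5) * resolution, y0 + (iy + 0.5) * resolution); invalid
    pixels hold NaN and are excluded from ``peak``.
    """

    values: np.ndarray  # (H, W) float
    valid: np.ndarray  # (H, W) bool
    resolution: float  # cm per pixel
    origin: tuple[float, float]  # (x0, y0) of the grid's lower-left corner
    cell_id: int = 0
    head_direction: str = "averaged"

    @property
    def peak(self) -> float:
        vals = self.values[self.valid]
        return float(np.nanmax(vals)) if vals.size else float("nan")

    def pixel_centers(self):
        h, w = self.values.shape
        x = self.origin[0] + (np.arange(w) + 0.5) * self.resolution
        y = self.origin[1] + (np.arange(h) + 0.5) * self.resolution
        return x, y


@dataclass
class SpikeRecord:
    """Artificial spikes emitted along a trajectory by one output cell."""

    spike_positions: np.ndarray  # (n_spikes, 2)
    cell_id: int
    n_steps: int
    #: trajectory step index of each spike (None for hand-built records)
    spike_steps: np.ndarray | None = None

    def subset(self, step_mask: np.ndarray) -> "SpikeRecord":
        """Spikes emitted during the selected trajectory steps."""
        if self.spike_steps is None:
            raise ValueError("record carries no step indices")
        keep = step_mask[self.spike_steps]
        return SpikeRecord(self.spike_positions[keep], self.cell_id,
                           int(step_mask.sum()), self.spike_steps[keep])


# ---------------------------------------------------------------------------
# dense grid sampling


def _grid_mask(maze: MazeSpec, resolution: float, margin: float):
    x0, y0, x1, y1 = maze.floor_bounds
    w = int(np.ceil((x1 - x0) / resolution))
    h = int(np.ceil((y1 - y0) / resolution))
    xs = x0 + (np.arange(w) + 0.5) * resolution
    ys = y0 + (np.arange(h) + 0.5) * resolution
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    mask = contains(maze, pts, margin).reshape(h, w)
    return mask, pts, (x0, y0)


def sample_fixed_direction(
    net: NetworkModel,
    maze: MazeSpec,
    direction: str,
    resolution: float = 1.0,
    margin: float = 5.0,
    cam: CameraModel | None = None,
) -> list[RateMap]:
    """One map per output cell, the agent facing a fixed compass direction
    at every reachable grid point."""
    maps = sample_direction_set(net, maze, [direction], resolution, margin, cam)
    return maps[direction]


def sample_direction_set(
    net: NetworkModel,
    maze: MazeSpec,
    directions: list[str],
    resolution: float = 1.0,
    margin: float = 5.0,
    cam: CameraModel | None = None,
) -> dict[str, list[RateMap]]:
    """Dense maps for several fixed head directions, sharing the grid mask."""
    if not net.trained:
        raise ValueError("network is not fully trained")
    for d in directions:
        if d not in COMPASS:
            raise ValueError(f"unknown compass direction {d!r}")
    mask, pts, origin = _grid_mask(maze, resolution, margin)
    flat = mask.ravel()
    poses = pts[flat]
    out: dict[str, list[RateMap]] = {}
    n_cells = net.arch.ica_out
    # render/propagate in pose chunks so full-resolution arenas (tens of
    # thousands of poses) never hold all frames in memory at once
    chunk = max(1, int(50_000_000 // max(np.prod(net.arch.frame_shape), 1)))
    for d in directions:
        acts = np.empty((len(poses), n_cells), dtype=float)
        for i0 in range(0, len(poses), chunk):
            i1 = min(len(poses), i0 + chunk)
            frames = render_poses(maze, poses[i0:i1],
                                  np.full(i1 - i0, COMPASS[d]), cam,
                                  check_inside=False)
            acts[i0:i1] = forward_stream(net, frames)
        maps = []
        for c in range(n_cells):
            vals = np.full(mask.shape, np.nan)
            vals[mask] = acts[:, c]
            maps.append(RateMap(vals, mask.copy(), resolution, origin, c, d))
        out[d] = maps
    return out


def average_map(maps: list[RateMap]) -> RateMap:
    """Pixelwise mean over directional maps on their common valid mask."""
    if not maps:
        raise ValueError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        if m.values.shape != first.values.shape or not np.array_equal(m.valid, first.valid):
            raise ValueError("maps have inconsistent grids or masks")
        if m.cell_id != first.cell_id:
            raise ValueError("maps belong to different cells")
    stack = np.stack([m.values for m in maps])
    vals = np.full(first.values.shape, np.nan)
    vals[first.valid] = stack[:, first.valid].mean(axis=0)
    return RateMap(vals, first.valid.copy(), first.resolution, first.origin,
                   first.cell_id, "averaged")


# ---------------------------------------------------------------------------
# spike emulation and occupancy maps


def emulate_spikes(
    activities: np.ndarray,
    traj: Trajectory,
    rng: np.random.Generator | None = None,
    peaks: np.ndarray | None = None,
) -> list[SpikeRecord]:
    """Turn activities (T, n_cells) into artificial spikes along ``traj``.

    Negative activities are rectified at zero; each step then spikes with
    probability a / peak where the peak is the cell's full-pass maximum
    over the whole trajectory (so the procedure is deterministic given the
    random state and invariant to positive rescaling of the cell).  When
    one cell is sampled over several trajectories, pass the shared
    ``peaks`` so all its maps live on one rate scale.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    activities = np.asarray(activities, dtype=float)
    if activities.shape[0] != len(traj):
        raise ValueError("activities and trajectory length differ")
    a = np.clip(activities, 0.0, None)
    peaks = a.max(axis=0) if peaks is None else np.asarray(peaks, dtype=float)
    records = []
    for c in range(a.shape[1]):
        if peaks[c] <= 0.0:
            records.append(SpikeRecord(np.empty((0, 2)), c, len(traj),
                                       np.empty(0, dtype=int)))
            continue
        p = np.clip(a[:, c] / peaks[c], 0.0, 1.0)
        fire = rng.random(len(p)) < p
        steps = np.nonzero(fire)[0]
        records.append(SpikeRecord(traj.positions[fire].copy(), c, len(traj),
                                   steps))
    return records


def _map_grid(bounds, bin_size):
    x0, y0, x1, y1 = bounds
    w = int(np.ceil((x1 - x0) / bin_size))
    h = int(np.ceil((y1 - y0) / bin_size))
    xe = x0 + np.arange(w + 1) * bin_size
    ye = y0 + np.arange(h + 1) * bin_size
    return xe, ye


def bin_and_smooth(
    spikes: SpikeRecord,
    traj: Trajectory,
    bin_size: float = 3.0,
    kernel_width: float = 3.0,
    bounds: tuple[float, float, float, float] | None = None,
) -> RateMap:
    """Spike count / occupancy time per bin, Gaussian-smoothed over the
    visited mask (the kernel is renormalised at mask edges so total rate
    mass is conserved); unvisited bins are invalid."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if bounds is None:
        pos = traj.positions
        pad = bin_size
        bounds = (pos[:, 0].min() - pad, pos[:, 1].min() - pad,
                  pos[:, 0].max() + pad, pos[:, 1].max() + pad)
    xe, ye = _map_grid(bounds, bin_size)
    occ, _, _ = np.histogram2d(traj.positions[:, 1], traj.positions[:, 0], bins=(ye, xe))
    occ *= traj.dt
    cnt, _, _ = np.histogram2d(spikes.spike_positions[:, 1], spikes.spike_positions[:, 0],
                               bins=(ye, xe))
    visited = occ > 0
    rate = np.zeros_like(occ)
    rate[visited] = cnt[visited] / occ[visited]
    sigma = kernel_width / bin_size
    num = gaussian_filter(np.where(visited, rate, 0.0), sigma, mode="constant")
    den = gaussian_filter(visited.astype(float), sigma, mode="constant")
    smooth = np.full(occ.shape, np.nan)
    smooth[visited] = num[visited] / den[visited]
    return RateMap(smooth, visited, bin_size, (bounds[0], bounds[1]),
                   spikes.cell_id, "averaged")


def occupancy_limited_map(
    activities: np.ndarray,
    traj: Trajectory,
    cutoff_time: float,
    rng: np.random.Generator | None = None,
    bin_size: float = 3.0,
    kernel_width: float = 3.0,
    bounds: tuple[float, float, float, float] | None = None,
) -> list[RateMap]:
    """Ratemaps using only the part of the trajectory before ``cutoff_time``
    (the valid mask shrinks to the bins actually visited by then)."""
    if cutoff_time > traj.duration + 1e-9:
        raise ValueError("cutoff beyond trajectory duration")
    n = int(round(cutoff_time / traj.dt))
    sub = truncate(traj, cutoff_time)
    sub_acts = np.asarray(activities)[:n]
    records = emulate_spikes(sub_acts, sub, rng)
    return [bin_and_smooth(r, sub, bin_size, kernel_width, bounds) for r in records]


def trajectory_ratemaps(
    activities: np.ndarray,
    traj: Trajectory,
    rng: np.random.Generator | None = None,
    bin_size: float = 3.0,
    kernel_width: float = 3.0,
    bounds: tuple[float, float, float, float] | None = None,
) -> list[RateMap]:
    """Full spike-emulation pipeline for every cell along one trajectory."""
    records = emulate_spikes(activities, traj, rng)
    return [bin_and_smooth(r, traj, bin_size, kernel_width, bounds) for r in records]
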