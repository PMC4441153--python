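"""Panoramic frame rendering by per-column 2-D ray casting.

The virtual rat sees a grayscale strip covering a 320-degree azimuthal field
of view (1 degree per pixel column at full resolution) and a narrow vertical
slice around the horizon.  Because walls never vary along the vertical axis,
a 2-D ray cast per column plus a perspective vertical projection (apparent
wall height proportional to wall_height / distance) reproduces everything a
full 3-D rasteriser would show in this setting.

Each column ray finds the nearest wall intersection; pixel rows whose
elevation falls onto the wall face sample the wall's procedural texture (or
a cue card, if one covers the hit point), rows below show the floor, and
rows above show the background: a black curtain or a procedural 360-degree
"office panorama" rendered on a distant cylinder, which yields genuine
parallax.  All patterns are deterministic, so identical (maze, pose, camera)
always produce bitwise-identical frames.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass

import numpy as np

from .environment import MazeSpec, contains

__all__ = [
    "CameraModel",
    "Frame",
    "render_frame",
    "render_poses",
    "render_stream",
    "cast_rays",
    "save_stream",
    "load_stream",
]

_FLOOR_COLOR = 0.42
_CURTAIN_COLOR = 0.03


@dataclass(frozen=True)
class CameraModel:
    """Panoramic camera: azimuthal FoV split into equal columns, vertical rows
    spanning ±``elevation_half_deg`` around the horizon at ``eye_height`` cm."""

    n_columns: int = 320
    n_rows: int = 40
    fov_azimuth: float = 320.0
    eye_height: float = 3.0
    elevation_half_deg: float = 20.0
    background_distance: float = 500.0

    @property
    def degrees_per_column(self) -> float:
        return self.fov_azimuth / self.n_columns

    def column_azimuths(self, heading: float) -> np.ndarray:
        """Azimuth (deg, CCW from east) of each column's ray for a heading.

        Column c covers heading + (c - (n_columns - 1)/2) * degrees_per_column,
        so the field of view is centred on the heading.
        """
        c = np.arange(self.n_columns)
        return heading + (c - (self.n_columns - 1) / 2.0) * self.degrees_per_column

    def row_elevations(self) -> np.ndarray:
        """Elevation (radians) of each row centre, top row first."""
        half = math.radians(self.elevation_half_deg)
        r = np.arange(self.n_rows)
        return half - (r + 0.5) * (2 * half / self.n_rows)


@dataclass(frozen=True)
class Frame:
    pixels: np.ndarray  # (n_rows, n_columns) float32 in [0, 1]
    pose: tuple[tuple[float, float], float]


# ---------------------------------------------------------------------------
# procedural textures


def _tex_plain(s, z):
    return np.full(np.broadcast(s, z).shape, 0.5)


def _tex_light(s, z):
    return np.full(np.broadcast(s, z).shape, 0.62)


def _tex_stripes(s, z):
    return 0.5 + 0.28 * np.sin(2 * np.pi * s / 21.0) + 0.0 * z


def _tex_checker(s, z):
    return 0.5 + 0.25 * np.sin(2 * np.pi * s / 16.0) * np.sin(2 * np.pi * z / 10.0)


def _tex_rough(s, z):
    # fixed-phase sum of incommensurate sinusoids: looks like mottled plaster
    return (
        0.5
        + 0.15 * np.sin(0.61 * s + 1.7)
        + 0.10 * np.sin(1.37 * s + 0.3) * np.sin(0.83 * z + 2.2)
        + 0.08 * np.sin(0.23 * s + 4.1)
    )


TEXTURES = {
    "plain": _tex_plain,
    "light": _tex_light,
    "stripes": _tex_stripes,
    "checker": _tex_checker,
    "rough": _tex_rough,
}


def _panorama(az: np.ndarray, elev: np.ndarray) -> np.ndarray:
    """Office-panorama stand-in: smooth azimuthal pattern with a vertical
    gradient, defined on the full background cylinder."""
    return (
        0.5
        + 0.20 * np.sin(2 * az + 1.3)
        + 0.13 * np.sin(5 * az + 0.4)
        + 0.08 * np.sin(9 * az + 2.6)
        + 0.10 * np.sin(3 * az + 0.9) * np.cos(2 * elev)
        + 0.25 * elev
    )


# ---------------------------------------------------------------------------
# maze geometry cache


class _MazeArrays:
    def __init__(self, maze: MazeSpec):
        walls = maze.walls
        self.a = np.array([w.start for w in walls], dtype=float)
        b = np.array([w.end for w in walls], dtype=float)
        self.d = b - self.a
        self.seg_len = np.hypot(self.d[:, 0], self.d[:, 1])
        self.height = np.array([w.height for w in walls], dtype=float)
        self.s0 = np.array([w.s0 for w in walls], dtype=float)
        tex_ids = sorted({w.texture_id for w in walls})
        self.tex_ids = tex_ids
        self.tex_idx = np.array([tex_ids.index(w.texture_id) for w in walls])
        wall_ids = sorted({w.wall_id for w in walls})
        wid_index = {w: i for i, w in enumerate(wall_ids)}
        self.wall_idx = np.array([wid_index[w.wall_id] for w in walls])
        # active cue cards as (wall_index, s_lo, s_hi, color)
        self.cues = [
            (wid_index[c.host_wall], c.offset, c.offset + c.length, c.color)
            for c in maze.cues
            if c.present and c.host_wall in wid_index
        ]


def _maze_arrays(maze: MazeSpec) -> _MazeArrays:
    cache = getattr(maze, "_render_arrays", None)
    if cache is None:
        cache = _MazeArrays(maze)
        maze._render_arrays = cache
    return cache


# ---------------------------------------------------------------------------
# ray casting


def cast_rays(maze: MazeSpec, origins: np.ndarray, azimuths_deg: np.ndarray):
    """Intersect rays with the maze walls.

    ``origins``: (n, 2) ray start points; ``azimuths_deg``: (n,) directions.
    Returns ``(dist, seg_idx, wall_s)`` where ``dist`` is the distance to the
    nearest wall hit (inf if none), ``seg_idx`` the wall-segment index and
    ``wall_s`` the arc-length coordinate of the hit along its logical wall.
    """
    ma = _maze_arrays(maze)
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    az = np.radians(np.asarray(azimuths_deg, dtype=float))
    u = np.stack([np.cos(az), np.sin(az)], axis=-1)  # (n, 2)

    ap = ma.a[None, :, :] - origins[:, None, :]  # (n, S, 2)
    dx, dy = ma.d[:, 0], ma.d[:, 1]
    denom = u[:, None, 0] * dy[None, :] - u[:, None, 1] * dx[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ap[:, :, 0] * dy[None, :] - ap[:, :, 1] * dx[None, :]) / denom
        s = (ap[:, :, 0] * u[:, None, 1] - ap[:, :, 1] * u[:, None, 0]) / denom
    valid = (np.abs(denom) > 1e-12) & (t > 1e-9) & (s >= -1e-9) & (s <= 1 + 1e-9)
    t = np.where(valid, t, np.inf)
    seg_idx = np.argmin(t, axis=1)
    rows = np.arange(len(seg_idx))
    dist = t[rows, seg_idx]
    frac = np.clip(s[rows, seg_idx], 0.0, 1.0)
    wall_s = ma.s0[seg_idx] + frac * ma.seg_len[seg_idx]
    return dist, seg_idx, wall_s


def _shade_rays(maze, cam, origins, az_deg):
    """Colour an (n,) batch of rays into an (n, n_rows) pixel block."""
    ma = _maze_arrays(maze)
    dist, seg_idx, wall_s = cast_rays(maze, origins, az_deg)
    if not np.all(np.isfinite(dist)):
        raise ValueError("ray escaped the arena; pose outside maze?")
    n = len(dist)
    elev = cam.row_elevations()  # (R,)
    tan_e = np.tan(elev)
    z = cam.eye_height + dist[:, None] * tan_e[None, :]  # (n, R) wall-plane height
    h_seg = ma.height[seg_idx]

    out = np.empty((n, cam.n_rows), dtype=float)
    # floor below the wall base
    out[:] = _FLOOR_COLOR
    # wall face
    wall_mask = (z >= 0.0) & (z <= h_seg[:, None])
    tex_of_ray = ma.tex_idx[seg_idx]
    for ti, tex_id in enumerate(ma.tex_ids):
        sel = tex_of_ray == ti
        if not np.any(sel):
            continue
        block = TEXTURES[tex_id](wall_s[sel, None], z[sel])
        out[sel] = np.where(wall_mask[sel], block, out[sel])
    # cue cards override their wall span (full height)
    wall_of_ray = ma.wall_idx[seg_idx]
    for wid, lo, hi, color in ma.cues:
        sel = (wall_of_ray == wid) & (wall_s >= lo) & (wall_s <= hi)
        if np.any(sel):
            out[sel] = np.where(wall_mask[sel], color, out[sel])
    # background above the wall top
    above = z > h_seg[:, None]
    if np.any(above):
        if maze.background == "curtain":
            out[above] = _CURTAIN_COLOR
        else:
            az = np.radians(np.asarray(az_deg, dtype=float))
            u = np.stack([np.cos(az), np.sin(az)], axis=-1)
            # ray / background-cylinder intersection for parallax
            b = np.einsum("ij,ij->i", origins, u)
            c = np.einsum("ij,ij->i", origins, origins) - cam.background_distance**2
            t_bg = -b + np.sqrt(np.maximum(b * b - c, 0.0))
            hit = origins + t_bg[:, None] * u
            az_bg = np.arctan2(hit[:, 1], hit[:, 0])
            pano = _panorama(az_bg[:, None], elev[None, :])
            out = np.where(above, np.broadcast_to(pano, out.shape), out)
    return np.clip(out, 0.0, 1.0)


def render_poses(
    maze: MazeSpec,
    positions: np.ndarray,
    headings: np.ndarray,
    cam: CameraModel | None = None,
    check_inside: bool = True,
) -> np.ndarray:
    """Render frames for many poses at once; returns (n, n_rows, n_columns)."""
    cam = cam or CameraModel()
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    headings = np.atleast_1d(np.asarray(headings, dtype=float))
    if check_inside and not np.all(contains(maze, positions, 0.0)):
        raise ValueError("pose outside arena")
    n = len(positions)
    C = cam.n_columns
    S = max(len(maze.walls), 1)
    out = np.empty((n, cam.n_rows, C), dtype=np.float32)
    col_off = (np.arange(C) - (C - 1) / 2.0) * cam.degrees_per_column
    chunk = max(1, int(4_000_000 // (C * S)))
    for i0 in range(0, n, chunk):
        i1 = min(n, i0 + chunk)
        m = i1 - i0
        az = (headings[i0:i1, None] + col_off[None, :]).ravel()
        orig = np.repeat(positions[i0:i1], C, axis=0)
        block = _shade_rays(maze, cam, orig, az)  # (m*C, R)
        out[i0:i1] = block.reshape(m, C, cam.n_rows).transpose(0, 2, 1)
    return out


def render_frame(
    maze: MazeSpec,
    pose: tuple[tuple[float, float], float],
    cam: CameraModel | None = None,
) -> Frame:
    """Render a single pose ``((x, y), heading_deg)`` into a Frame."""
    (x, y), heading = pose
    cam = cam or CameraModel()
    pixels = render_poses(maze, [(x, y)], [heading], cam)[0]
    return Frame(pixels=pixels, pose=((x, y), heading))


def render_stream(maze: MazeSpec, traj, cam: CameraModel | None = None) -> np.ndarray:
    """Render one frame per trajectory sample; returns (T, n_rows, n_columns)."""
    return render_poses(maze, traj.positions, traj.headings, cam)


# ---------------------------------------------------------------------------
# binary stream files

_MAGIC = b"SPST"


def save_stream(path, frames: np.ndarray) -> None:
    """Write frames as a small-header contiguous float32 file."""
    frames = np.ascontiguousarray(frames, dtype=np.float32)
    n, rows, cols = frames.shape
    with open(path, "wb") as fh:
        fh.write(_MAGIC + struct.pack("<III", n, rows, cols))
        fh.write(frames.tobytes())


def load_stream(path) -> np.ndarray:
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise ValueError("not a frame-stream file")
        n, rows, cols = struct.unpack("<III", fh.read(12))
        data = np.frombuffer(fh.read(), dtype=np.float32)
    return data.reshape(n, rows, cols).copy()
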