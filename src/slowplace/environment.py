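"""Declarative 2-D maze specifications for the virtual-rat experiments.

An arena is a single-level, singly connected floor region bounded by wall
polylines.  Coordinates are continuous, in centimetres, with the origin at
the arena centroid; the y-axis points north and headings are measured in
degrees counter-clockwise from east.

Walls carry a height (look-over arenas use low walls, curtained/ceiling
arenas use walls tall enough to block the view) and a procedural texture
identifier.  Cue cards are white (or otherwise coloured) patches attached
to a named wall; toggling a card's ``present`` flag changes rendering only,
never the walkable geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import shapely
import yaml
from shapely.geometry import Polygon

__all__ = [
    "WallSegment",
    "CueCard",
    "MazeSpec",
    "make_standard_arena",
    "contains",
    "LOOK_OVER_HEIGHT",
    "TALL_WALL_HEIGHT",
]

#: wall height (cm) for arenas the agent can peek over
LOOK_OVER_HEIGHT = 25.0
#: wall height (cm) that fully blocks the 40-row vertical field of view
TALL_WALL_HEIGHT = 100.0


@dataclass(frozen=True)
class WallSegment:
    """One straight wall piece.

    ``wall_id`` names the logical wall the segment belongs to (e.g. ``"north"``
    for one side of a box, ``"rim"`` for a discretised circle); ``s0`` is the
    cumulative arc length (cm) of the segment's start along that logical wall,
    which is the coordinate cue cards are positioned in.  ``loop_id`` groups
    segments into closed boundary loops (loop 0 is the outer boundary,
    higher loops are interior obstacles).
    """

    start: tuple[float, float]
    end: tuple[float, float]
    height: float
    texture_id: str = "plain"
    wall_id: str = "wall"
    s0: float = 0.0
    loop_id: int = 0

    def __post_init__(self) -> None:
        if self.start == self.end:
            raise ValueError("degenerate wall segment: start == end")
        if self.height <= 0:
            raise ValueError("wall height must be positive")

    @property
    def length(self) -> float:
        return math.hypot(self.end[0] - self.start[0], self.end[1] - self.start[1])


@dataclass(frozen=True)
class CueCard:
    """A coloured card spanning ``[offset, offset + length]`` cm along a wall."""

    host_wall: str
    offset: float
    length: float
    color: float = 1.0
    present: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("cue card length must be positive")


@dataclass
class MazeSpec:
    """Parametric maze: wall segments, cue cards, background, floor bounds."""

    walls: list[WallSegment]
    cues: list[CueCard] = field(default_factory=list)
    #: ``"curtain"`` (black surround) or ``"panorama"`` (office strip with parallax)
    background: str = "panorama"
    name: str = "maze"

    def __post_init__(self) -> None:
        self._region = None
        self._validate_cues()

    # -- geometry ----------------------------------------------------------

    def _loops(self) -> list[list[tuple[float, float]]]:
        loops: dict[int, list[WallSegment]] = {}
        for w in self.walls:
            loops.setdefault(w.loop_id, []).append(w)
        out = []
        for lid in sorted(loops):
            segs = loops[lid]
            out.append([s.start for s in segs])
        return out

    @property
    def region(self) -> Polygon:
        """Walkable floor region (outer boundary minus obstacle loops)."""
        if self._region is None:
            loops = self._loops()
            polys = [Polygon(lp) for lp in loops]
            outer = max(polys, key=lambda p: p.area)
            holes = [p for p in polys if p is not outer]
            self._region = Polygon(
                outer.exterior.coords, [h.exterior.coords for h in holes]
            )
        return self._region

    @property
    def floor_bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer boundary, in cm."""
        return self.region.bounds

    @property
    def wall_height_blocks_view(self) -> bool:
        return min(w.height for w in self.walls) >= TALL_WALL_HEIGHT

    def wall_length(self, wall_id: str) -> float:
        total = 0.0
        for w in self.walls:
            if w.wall_id == wall_id:
                total = max(total, w.s0 + w.length)
        if total == 0.0:
            raise KeyError(f"unknown wall_id {wall_id!r}")
        return total

    def _validate_cues(self) -> None:
        for c in self.cues:
            if not (0.0 <= c.offset and c.offset + c.length <= self.wall_length(c.host_wall) + 1e-9):
                raise ValueError(
                    f"cue card on {c.host_wall!r} exceeds its host wall"
                )

    # -- cue manipulation --------------------------------------------------

    def with_cues(self, present: Sequence[bool]) -> "MazeSpec":
        """Copy of the maze with per-cue presence flags replaced."""
        if len(present) != len(self.cues):
            raise ValueError("presence flag count mismatch")
        cues = [replace(c, present=p) for c, p in zip(self.cues, present)]
        return MazeSpec(self.walls, cues, self.background, self.name)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "background": self.background,
            "walls": [
                {
                    "start": list(w.start),
                    "end": list(w.end),
                    "height": w.height,
                    "texture_id": w.texture_id,
                    "wall_id": w.wall_id,
                    "s0": w.s0,
                    "loop_id": w.loop_id,
                }
                for w in self.walls
            ],
            "cues": [
                {
                    "host_wall": c.host_wall,
                    "offset": c.offset,
                    "length": c.length,
                    "color": c.color,
                    "present": c.present,
                }
                for c in self.cues
            ],
        }

    def dumps(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "MazeSpec":
        walls = [
            WallSegment(
                tuple(w["start"]), tuple(w["end"]), w["height"],
                w["texture_id"], w["wall_id"], w["s0"], w["loop_id"],
            )
            for w in d["walls"]
        ]
        cues = [
            CueCard(c["host_wall"], c["offset"], c["length"], c["color"], c["present"])
            for c in d["cues"]
        ]
        return cls(walls, cues, d["background"], d["name"])

    @classmethod
    def loads(cls, text: str) -> "MazeSpec":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# loop builders


def _loop_walls(
    points: list[tuple[float, float]],
    height: float,
    texture_id: str,
    wall_ids: Sequence[str] | str,
    loop_id: int = 0,
) -> list[WallSegment]:
    """Close ``points`` into wall segments.  ``wall_ids`` is either one id for
    the whole loop (arc length accumulates across segments) or one id per
    segment (each segment starts its own arc-length coordinate)."""
    n = len(points)
    per_segment = not isinstance(wall_ids, str)
    walls = []
    s = 0.0
    for i in range(n):
        a, b = points[i], points[(i + 1) % n]
        wid = wall_ids[i] if per_segment else wall_ids
        s0 = 0.0 if per_segment else s
        walls.append(WallSegment(a, b, height, texture_id, wid, s0, loop_id))
        s += math.hypot(b[0] - a[0], b[1] - a[1])
    return walls


def _rectangle_loop(
    w: float, h: float, height: float, texture_id: str = "plain", loop_id: int = 0,
    center: tuple[float, float] = (0.0, 0.0),
) -> list[WallSegment]:
    """Axis-aligned box centred on ``center``; sides named south/east/north/west.

    Corners are ordered counter-clockwise so the interior lies to the left.
    """
    cx, cy = center
    x0, x1 = cx - w / 2, cx + w / 2
    y0, y1 = cy - h / 2, cy + h / 2
    pts = [(x0, y0), (x1, y0), (x1, y1), (x0, y1)]
    ids = [f"south", f"east", f"north", f"west"]
    if loop_id:
        ids = [f"{i}_{loop_id}" for i in ids]
    return _loop_walls(pts, height, texture_id, ids, loop_id)


def _superellipse_points(
    a: float, b: float, exponent: float, n: int
) -> list[tuple[float, float]]:
    pts = []
    for i in range(n):
        th = 2 * math.pi * i / n
        c, s = math.cos(th), math.sin(th)
        r = (abs(c / a) ** exponent + abs(s / b) ** exponent) ** (-1.0 / exponent)
        pts.append((r * c, r * s))
    return pts


def _circle_loop(
    r: float, height: float, texture_id: str = "plain", n: int = 360,
    wall_id: str = "rim",
) -> list[WallSegment]:
    pts = _superellipse_points(r, r, 2.0, n)
    return _loop_walls(pts, height, texture_id, wall_id)


def arc_to_cm(r: float, degrees: float) -> float:
    """Arc length (cm) subtended by ``degrees`` on a radius-``r`` circular rim."""
    return r * math.radians(degrees)


def circular_cue(r: float, center_deg: float, arc_deg: float, color: float = 1.0) -> CueCard:
    """Cue card covering ``arc_deg`` of rim centred on azimuth ``center_deg``.

    Rim arc length starts at azimuth 0 (east) and accumulates counter-clockwise.
    """
    start_deg = (center_deg - arc_deg / 2) % 360.0
    return CueCard("rim", arc_to_cm(r, start_deg), arc_to_cm(r, arc_deg), color)


# ---------------------------------------------------------------------------
# standard arenas

# four intermediate stages plus the two familiar endpoints
MORPH_STAGES = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

_MORPH_SQUARE_SIDE = 62.0
_MORPH_CIRCLE_RADIUS = 39.0


def make_standard_arena(
    kind: str,
    params: Sequence[float],
    *,
    wall_height: float | None = None,
    texture_id: str = "plain",
    background: str = "panorama",
    circle_segments: int = 360,
) -> MazeSpec:
    """Build one of the protocol arena geometries.

    kinds: ``square [side]``, ``rectangle [w, h]``, ``circle [radius]``,
    ``linear_track [length, width]``, ``morph_stage [t]`` with the morph
    parameter t in [0, 1] interpolating a superellipse family from the 62 cm
    square (t=0) to the radius-39 cm circle (t=1).
    """
    params = list(params)
    if kind != "morph_stage" and any(p <= 0 for p in params):
        raise ValueError("arena dimensions must be positive")
    h = wall_height if wall_height is not None else LOOK_OVER_HEIGHT
    if kind == "square":
        (side,) = params
        walls = _rectangle_loop(side, side, h, texture_id)
        name = f"square_{side:g}"
    elif kind == "rectangle":
        w, d = params
        walls = _rectangle_loop(w, d, h, texture_id)
        name = f"rect_{w:g}x{d:g}"
    elif kind == "linear_track":
        length, width = params
        walls = _rectangle_loop(length, width, h, texture_id)
        name = f"track_{length:g}x{width:g}"
    elif kind == "circle":
        (r,) = params
        walls = _circle_loop(r, h, texture_id, circle_segments)
        name = f"circle_r{r:g}"
    elif kind == "morph_stage":
        (t,) = params
        if not 0.0 <= t <= 1.0:
            raise ValueError("morph parameter must lie in [0, 1]")
        if t == 0.0:
            walls = _rectangle_loop(_MORPH_SQUARE_SIDE, _MORPH_SQUARE_SIDE, h, texture_id)
        else:
            # exponent interpolated through 1/p so t=1 is the exact circle and
            # small t approaches the square corner-first
            p = 2.0 / t
            a = _MORPH_SQUARE_SIDE / 2 + (_MORPH_CIRCLE_RADIUS - _MORPH_SQUARE_SIDE / 2) * t
            pts = _superellipse_points(a, a, p, circle_segments)
            walls = _loop_walls(pts, h, texture_id, "rim")
        name = f"morph_{t:g}"
    else:
        raise ValueError(f"unknown arena kind {kind!r}")
    return MazeSpec(walls, [], background, name)


# ---------------------------------------------------------------------------
# containment


def contains(maze: MazeSpec, p, margin: float = 0.0):
    """True iff ``p`` lies inside the walkable region, at least ``margin`` cm
    from every wall.  Accepts one point ``(x, y)`` or an (n, 2) array; returns
    a bool or a boolean array accordingly.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    pts = np.asarray(p, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    region = maze.region
    inside = shapely.contains(region, geoms)
    if margin > 0.0:
        dist = shapely.distance(region.boundary, geoms)
        inside &= dist >= margin
    return bool(inside[0]) if scalar else inside
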