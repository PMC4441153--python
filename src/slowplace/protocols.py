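"""Drivers for the simulated experiments.

Each driver wires environment -> motion -> renderer -> hierarchy ->
ratemaps -> metrics with the protocol's arena geometry, behaviour and
duration:

* development (A): five networks trained on nested prefixes of one
  trajectory in a 60x60 cm box, cells matched across networks;
* development (B): one network in a radius-40 cm cylinder, ratemaps built
  from spikes restricted to increasingly long trajectory prefixes;
* cue rotation: radius-76 cm cylinder with a single 90-degree white cue
  arc; maps sampled before and after rotating the cue by 90 degrees;
* cue removal: 83 cm square (ceiling-high walls) with three white cue
  cards of length 12, 40 and 69 cm on the east, west and south wall;
  maps sampled with different cue subsets removed;
* linear track: 80x12 cm corridor traversed end-to-end with noisy waypoint
  following; per-direction maps and silent/uni-/bidirectional counts;
* rhombus track: rhombus path inside a radius-38 cm arena, sampled
  clockwise and counter-clockwise;
* morph: joint training in a 62 cm square and a radius-39 cm circle, then
  sampling across six morph stages;
* stretch: training in a 120x60 cm rectangle, sampling in four scaled
  variants.

All drivers share one generically pretrained base network (lower layers
are experiment-independent) and derive every random stream from the run
seed, so identical configurations reproduce bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import (
    LOOK_OVER_HEIGHT,
    TALL_WALL_HEIGHT,
    CueCard,
    MazeSpec,
    MORPH_STAGES,
    _loop_walls,
    _rectangle_loop,
    circular_cue,
    make_standard_arena,
)
from .hierarchy import NetworkModel, experiment_train, forward_stream, generic_pretrain
from .metrics import (
    ConsistencyReport,
    classify_track_population,
    directional_consistency,
    field_rotation_deg,
    match_cells,
    segment_fields,
)
from .motion import BehaviorSpec, Trajectory, follow_waypoints, forage
from .ratemaps import (
    COMPASS,
    average_map,
    bin_and_smooth,
    emulate_spikes,
    occupancy_limited_map,
    sample_direction_set,
)
from .renderer import render_stream
from .workbench import Profile, RunConfig, SCALED_PROFILE, substream, substream_seed

__all__ = [
    "ProtocolResult",
    "generic_mazes",
    "pretrain_base",
    "run_development",
    "run_cue_rotation",
    "run_cue_removal",
    "run_linear_track",
    "run_rhombus",
    "run_morph",
    "run_stretch",
    "PROTOCOLS",
]


@dataclass
class ProtocolResult:
    config: RunConfig
    network: NetworkModel
    #: (variant, direction) -> list of 32 RateMaps
    maps: dict = field(default_factory=dict)
    #: variant -> ConsistencyReport
    reports: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# generic pretraining environments


def generic_mazes(profile: Profile) -> list[MazeSpec]:
    """Four view-blocking mazes with varied geometry and textures, used only
    to expose the lower layers to generic edges, corners and surfaces."""
    h = TALL_WALL_HEIGHT
    box = MazeSpec(_rectangle_loop(100, 80, h, "rough"), [], "curtain", "generic_box")

    # plus-shaped multi-arm maze (arm width 40, span 120)
    a, b = 20.0, 60.0
    plus_pts = [
        (a, a), (a, b), (-a, b), (-a, a), (-b, a), (-b, -a),
        (-a, -a), (-a, -b), (a, -b), (a, -a), (b, -a), (b, a),
    ]
    plus = MazeSpec(_loop_walls(plus_pts, h, "stripes", "arms"), [], "curtain",
                    "generic_plus")

    # large square littered with cube obstacles
    walls = _rectangle_loop(120, 120, h, "checker")
    for i, (cx, cy) in enumerate([(-30, -25), (25, 30), (30, -35)]):
        walls += _rectangle_loop(16, 16, h, "plain", loop_id=i + 1, center=(cx, cy))
    obstacles = MazeSpec(walls, [], "curtain", "generic_obstacles")

    # T-maze with one obstacle in the crossbar
    t_pts = [
        (-60, 40), (60, 40), (60, 10), (15, 10), (15, -70),
        (-15, -70), (-15, 10), (-60, 10),
    ]
    t_walls = _loop_walls(t_pts[::-1], h, "light", "twalls")
    t_walls += _rectangle_loop(12, 12, h, "stripes", loop_id=1, center=(35, 25))
    tmaze = MazeSpec(t_walls, [], "curtain", "generic_tmaze")
    return [box, plus, obstacles, tmaze]


def pretrain_base(profile: Profile, seed: int = 0) -> NetworkModel:
    """Generic pretraining: random foraging in four generic mazes, lower two
    layers fitted on the pooled streams and frozen."""
    mazes = generic_mazes(profile)
    frames_per_maze = profile.generic_frames // len(mazes)
    duration = frames_per_maze * profile.dt
    streams = []
    for i, maze in enumerate(mazes):
        rng = substream(seed, f"generic_traj_{i}")
        beh = BehaviorSpec(mode="forage", wall_margin=profile.wall_margin)
        traj = forage(maze, beh, duration, profile.dt, profile.speed, rng=rng)
        streams.append(render_stream(maze, traj, profile.camera))
    net = NetworkModel(arch=profile.arch)
    generic_pretrain(net, streams, profile.dt, seed=substream_seed(seed, "pretrain"))
    net.meta["pretrain_seed"] = seed
    return net


def _fresh_experiment_net(base: NetworkModel) -> NetworkModel:
    """New network sharing the frozen lower layers of ``base``."""
    return NetworkModel(arch=base.arch, layer1=base.layer1, layer2=base.layer2)


def _train(base, streams, profile, seed) -> NetworkModel:
    net = _fresh_experiment_net(base)
    experiment_train(net, streams, profile.dt, seed=substream_seed(seed, "train"))
    return net


# ---------------------------------------------------------------------------
# dense directional sampling + report


def directional_report(
    net: NetworkModel,
    maze: MazeSpec,
    profile: Profile,
    restrict_traj: Trajectory | None = None,
    margin: float | None = None,
):
    """8-direction dense maps, their averages, and the population report.

    If ``restrict_traj`` is given the valid mask is intersected with the
    map pixels actually visited by that trajectory (track protocols only
    analyse the area the agent covered in training).
    """
    margin = profile.wall_margin if margin is None else margin
    dirs = list(COMPASS)
    by_dir = sample_direction_set(net, maze, dirs, profile.map_resolution, margin,
                                  profile.camera)
    n_cells = len(by_dir[dirs[0]])
    # maps represent firing activity: rectify at zero (ICA sign convention
    # makes fields positive; negative excursions are not firing)
    for maps in by_dir.values():
        for m in maps:
            np.clip(m.values, 0.0, None, out=m.values)
    if restrict_traj is not None:
        ref = by_dir[dirs[0]][0]
        h, w = ref.values.shape
        x0, y0 = ref.origin
        res = ref.resolution
        ix = np.floor((restrict_traj.positions[:, 0] - x0) / res).astype(int)
        iy = np.floor((restrict_traj.positions[:, 1] - y0) / res).astype(int)
        visited = np.zeros((h, w), dtype=bool)
        ok = (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
        visited[iy[ok], ix[ok]] = True
        for maps in by_dir.values():
            for m in maps:
                m.valid &= visited
                m.values[~m.valid] = np.nan
    averaged = [average_map([by_dir[d][c] for d in dirs]) for c in range(n_cells)]
    dc = np.array([
        directional_consistency([by_dir[d][c] for d in dirs], averaged[c])
        for c in range(n_cells)
    ])
    counts = np.array([len(segment_fields(m)) for m in averaged])
    peaks = np.array([max(m.peak, 0.0) if np.isfinite(m.peak) else 0.0
                      for m in averaged])
    report = ConsistencyReport(dc, counts, peaks)
    return by_dir, averaged, report


def _store_directional(result, variant, by_dir, averaged):
    for d, maps in by_dir.items():
        result.maps[(variant, d)] = maps
    result.maps[(variant, "averaged")] = averaged


# ---------------------------------------------------------------------------
# protocol arenas


def _cue_rotation_maze(profile: Profile, cue_center_deg: float = 90.0) -> MazeSpec:
    # look-over walls with the black curtain visible beyond the rim: the
    # wall-top edge elevation is then a distance cue in every direction
    maze = make_standard_arena(
        "circle", [76.0], wall_height=LOOK_OVER_HEIGHT, background="curtain",
        circle_segments=profile.circle_segments,
    )
    maze.cues = [circular_cue(76.0, cue_center_deg, 90.0)]
    maze.name = f"cue_cylinder_{cue_center_deg:g}"
    return maze


def _cue_removal_maze(present=(True, True, True)) -> MazeSpec:
    maze = make_standard_arena("square", [83.0], wall_height=TALL_WALL_HEIGHT,
                               background="curtain")
    small, medium, large = 12.0, 40.0, 69.0
    maze.cues = [
        CueCard("east", (83 - small) / 2, small, 1.0, present[0]),
        CueCard("west", (83 - medium) / 2, medium, 1.0, present[1]),
        CueCard("south", (83 - large) / 2, large, 1.0, present[2]),
    ]
    maze.name = "cue_square"
    return maze


_CUE_SUBSETS = {
    "all": (True, True, True),
    "no_small": (False, True, True),
    "no_medium": (True, False, True),
    "no_large": (True, True, False),
    "only_small": (True, False, False),
    "only_medium": (False, True, False),
    "only_large": (False, False, True),
}


# ---------------------------------------------------------------------------
# drivers


def run_development(
    profile: Profile = SCALED_PROFILE,
    seed: int = 0,
    base: NetworkModel | None = None,
    variant: str = "box",
    duration: float = 480.0,
    cutoffs: tuple[float, ...] = (30.0, 60.0, 120.0, 240.0, 480.0),
) -> ProtocolResult:
    """Place-field development and sampling.

    Variant "box" trains one network per trajectory prefix (SFA cannot be
    paused and resumed) and chains cells to the final network by map
    matching; variant "cylinder" trains once and emits occupancy-limited
    spike maps at each cutoff.
    """
    if variant not in ("box", "cylinder"):
        raise ValueError("variant must be 'box' or 'cylinder'")
    if max(cutoffs) > duration:
        raise ValueError("prefix longer than trajectory")
    base = base if base is not None else pretrain_base(profile, seed)
    if variant == "box":
        maze = make_standard_arena("square", [60.0], wall_height=TALL_WALL_HEIGHT,
                                   background="curtain")
        maze.cues = [CueCard("north", 0.0, 60.0, 1.0)]  # white card covers north wall
    else:
        maze = make_standard_arena(
            "circle", [40.0], wall_height=TALL_WALL_HEIGHT, background="curtain",
            circle_segments=profile.circle_segments,
        )
        maze.cues = [circular_cue(40.0, 90.0, 90.0)]
    beh = BehaviorSpec(mode="forage", wall_margin=profile.wall_margin)
    traj = forage(maze, beh, duration, profile.dt, profile.speed,
                  rng=substream(seed, "traj"))
    frames = render_stream(maze, traj, profile.camera)

    cfg = RunConfig(protocol=f"development_{variant}", profile=profile.name, seed=seed,
                    overrides={"duration": duration, "cutoffs": list(cutoffs)})
    result = ProtocolResult(config=cfg, network=base)

    if variant == "box":
        nets, averaged_by_cutoff = [], {}
        for cut in cutoffs:
            n_frames = int(round(cut / profile.dt))
            net = _train(base, frames[:n_frames], profile, seed)
            nets.append(net)
            _, averaged, report = directional_report(net, maze, profile)
            averaged_by_cutoff[cut] = averaged
            result.maps[(f"t{cut:g}", "averaged")] = averaged
            result.reports[f"t{cut:g}"] = report
        ref = averaged_by_cutoff[cutoffs[-1]]
        matching = {}
        for cut in cutoffs[:-1]:
            perm, scores = match_cells(averaged_by_cutoff[cut], ref)
            matching[cut] = (perm, scores)
        result.network = nets[-1]
        result.extras["networks"] = nets
        result.extras["matching"] = matching
    else:
        net = _train(base, frames, profile, seed)
        result.network = net
        acts = forward_stream(net, frames)
        rng = substream(seed, "spikes")
        for cut in cutoffs:
            maps = occupancy_limited_map(
                acts, traj, cut, rng, profile.bin_size, profile.kernel_width,
                bounds=maze.floor_bounds,
            )
            result.maps[(f"t{cut:g}", "spike")] = maps
        result.extras["activities"] = acts
        result.extras["trajectory"] = traj
    return result


def run_cue_rotation(
    profile: Profile = SCALED_PROFILE,
    seed: int = 0,
    base: NetworkModel | None = None,
    duration: float = 480.0,
    rotation_deg: float = 90.0,
    sample_rotated: bool = True,
) -> ProtocolResult:
    """Radius-76 cm cylinder, single 90-degree cue arc, curtain surround;
    8 min of random exploration, then sampling with the cue in its original
    and rotated position."""
    base = base if base is not None else pretrain_base(profile, seed)
    maze = _cue_rotation_maze(profile, 90.0)
    beh = BehaviorSpec(mode="forage", wall_margin=profile.wall_margin)
    traj = forage(maze, beh, duration, profile.dt, profile.speed,
                  rng=substream(seed, "traj"))
    frames = render_stream(maze, traj, profile.camera)
    net = _train(base, frames, profile, seed)

    cfg = RunConfig(protocol="cue_rotation", profile=profile.name, seed=seed,
                    overrides={"duration": duration, "rotation_deg": rotation_deg})
    result = ProtocolResult(config=cfg, network=net)

    by_dir, averaged, report = directional_report(net, maze, profile)
    _store_directional(result, "original", by_dir, averaged)
    result.reports["original"] = report

    if sample_rotated:
        rotated = _cue_rotation_maze(profile, 90.0 + rotation_deg)
        by_dir_r, averaged_r, report_r = directional_report(net, rotated, profile)
        _store_directional(result, "rotated", by_dir_r, averaged_r)
        result.reports["rotated"] = report_r
        rotations = {}
        for c, (m0, m1) in enumerate(zip(averaged, averaged_r)):
            f0, f1 = segment_fields(m0), segment_fields(m1)
            if len(f0) == 1 and len(f1) == 1:
                rotations[c] = field_rotation_deg(f0[0].centroid, f1[0].centroid)
        result.extras["field_rotations"] = rotations
        if rotations:
            result.extras["median_rotation"] = float(np.median(list(rotations.values())))
    return result


def run_cue_removal(
    profile: Profile = SCALED_PROFILE,
    seed: int = 0,
    base: NetworkModel | None = None,
    duration: float = 720.0,
    variants: tuple[str, ...] = ("all", "no_small", "no_medium", "no_large",
                                 "only_small", "only_medium", "only_large"),
) -> ProtocolResult:
    """83 cm square with three white cue cards (12, 40, 69 cm on the east,
    west and south wall), 12 min exploration, then sampling with different
    cue subsets removed."""
    for v in variants:
        if v not in _CUE_SUBSETS:
            raise ValueError(f"unknown cue subset {v!r}")
    base = base if base is not None else pretrain_base(profile, seed)
    maze = _cue_removal_maze()
    beh = BehaviorSpec(mode="forage", wall_margin=profile.wall_margin)
    traj = forage(maze, beh, duration, profile.dt, profile.speed,
                  rng=substream(seed, "traj"))
    frames = render_stream(maze, traj, profile.camera)
    net = _train(base, frames, profile, seed)

    cfg = RunConfig(protocol="cue_removal", profile=profile.name, seed=seed,
                    overrides={"duration": duration, "variants": list(variants)})
    result = ProtocolResult(config=cfg, network=net)

    peaks = {}
    for v in variants:
        vmaze = _cue_removal_maze(_CUE_SUBSETS[v])
        by_dir, averaged, report = directional_report(net, vmaze, profile)
        _store_directional(result, v, by_dir, averaged)
        result.reports[v] = report
        peaks[v] = report.per_cell_peak
    if "all" in peaks:
        baseline = np.where(peaks["all"] > 0, peaks["all"], np.nan)
        result.extras["peak_ratio"] = {
            v: peaks[v] / baseline for v in variants if v != "all"
        }
    return result


def _split_by_heading(traj: Trajectory, axis_deg: float):
    """Boolean mask of samples moving within 90 degrees of ``axis_deg``."""
    d = (traj.headings - axis_deg + 180.0) % 360.0 - 180.0
    return np.abs(d) < 90.0


def _subset_traj(traj: Trajectory, mask: np.ndarray) -> Trajectory:
    return Trajectory(traj.positions[mask], traj.headings[mask], traj.dt, traj.speed)


def run_linear_track(
    profile: Profile = SCALED_PROFILE,
    seed: int = 0,
    base: NetworkModel | None = None,
    duration: float = 300.0,
    wall_margin: float = 4.0,
    waypoint_noise: float = 1.5,
) -> ProtocolResult:
    """80x12 cm corridor with look-over walls, traversed end-to-end for
    5 min; per-direction spike maps and the silent / unidirectional /
    bidirectional population split."""
    base = base if base is not None else pretrain_base(profile, seed)
    maze = make_standard_arena("linear_track", [80.0, 12.0],
                               wall_height=LOOK_OVER_HEIGHT, background="panorama")
    ends = [(-34.0, 0.0), (34.0, 0.0)]
    beh = BehaviorSpec(mode="waypoints", waypoints=ends,
                       waypoint_noise=waypoint_noise, wall_margin=wall_margin)
    traj = follow_waypoints(maze, beh, duration, profile.dt, profile.speed,
                            rng=substream(seed, "traj"))
    frames = render_stream(maze, traj, profile.camera)
    net = _train(base, frames, profile, seed)

    cfg = RunConfig(protocol="linear_track", profile=profile.name, seed=seed,
                    overrides={"duration": duration})
    result = ProtocolResult(config=cfg, network=net)

    # sampling run: fresh noisy traversals; spikes drawn on one per-cell
    # scale over the whole run, then split by motion direction
    straj = follow_waypoints(maze, beh, duration, profile.dt, profile.speed,
                             rng=substream(seed, "sample_traj"))
    acts = forward_stream(net, render_stream(maze, straj, profile.camera))
    east = _split_by_heading(straj, 0.0)
    rng = substream(seed, "spikes")
    records = emulate_spikes(acts, straj, rng)
    dir_maps = {}
    for name, mask in (("east", east), ("west", ~east)):
        sub = _subset_traj(straj, mask)
        dir_maps[name] = [
            bin_and_smooth(r.subset(mask), sub, profile.bin_size,
                           profile.kernel_width, bounds=maze.floor_bounds)
            for r in records
        ]
        result.maps[(name, "spike")] = dir_maps[name]
    labels = classify_track_population(dir_maps["east"], dir_maps["west"])
    result.extras["labels"] = labels
    result.extras["counts"] = {
        k: labels.count(k) for k in ("silent", "unidirectional", "bidirectional")
    }

    by_dir, averaged, report = directional_report(net, maze, profile,
                                                  margin=wall_margin)
    _store_directional(result, "track", by_dir, averaged)
    result.reports["track"] = report
    return result


def run_rhombus(
    profile: Profile = SCALED_PROFILE,
    seed: int = 0,
    base: NetworkModel | None = None,
    duration: float = 390.0,
    sample_duration: float = 180.0,
    vertex_radius: float = 27.0,
) -> ProtocolResult:
    """Rhombus path (vertices at 27 cm) inside a radius-38 cm textured
    arena, 6.5 min of noisy path following; maps sampled along clockwise
    and counter-clockwise traversals."""
    base = base if base is not None else pretrain_base(profile, seed)
    maze = make_standard_arena(
        "circle", [38.0], wall_height=LOOK_OVER_HEIGHT, background="panorama",
        circle_segments=profile.circle_segments, texture_id="rough",
    )
    r = vertex_radius
    verts = [(r, 0.0), (0.0, r), (-r, 0.0), (0.0, -r)]
    beh = BehaviorSpec(mode="waypoints", waypoints=verts, waypoint_noise=3.0,
                       wall_margin=profile.wall_margin)
    traj = follow_waypoints(maze, beh, duration, profile.dt, profile.speed,
                            rng=substream(seed, "traj"))
    frames = render_stream(maze, traj, profile.camera)
    net = _train(base, frames, profile, seed)

    cfg = RunConfig(protocol="rhombus", profile=profile.name, seed=seed,
                    overrides={"duration": duration})
    result = ProtocolResult(config=cfg, network=net)

    rng = substream(seed, "spikes")
    runs = {}
    for name, reverse in (("ccw", False), ("cw", True)):
        straj = follow_waypoints(maze, beh, sample_duration, profile.dt,
                                 profile.speed, rng=substream(seed, f"sample_{name}"),
                                 reverse=reverse)
        acts = forward_stream(net, render_stream(maze, straj, profile.camera))
        runs[name] = (straj, acts)
    # one per-cell rate scale across both traversal orientations
    peaks = np.maximum(np.clip(runs["ccw"][1], 0, None).max(0),
                       np.clip(runs["cw"][1], 0, None).max(0))
    dir_maps = {}
    for name, (straj, acts) in runs.items():
        records = emulate_spikes(acts, straj, rng, peaks=peaks)
        dir_maps[name] = [
            bin_and_smooth(rec, straj, profile.bin_size, profile.kernel_width,
                           bounds=maze.floor_bounds)
            for rec in records
        ]
        result.maps[(name, "spike")] = dir_maps[name]
    labels = classify_track_population(dir_maps["ccw"], dir_maps["cw"])
    result.extras["labels"] = labels
    result.extras["counts"] = {
        k: labels.count(k) for k in ("silent", "unidirectional", "bidirectional")
    }

    # consistency only within the area covered during training
    by_dir, averaged, report = directional_report(net, maze, profile,
                                                  restrict_traj=traj)
    _store_directional(result, "arena", by_dir, averaged)
    result.reports["arena"] = report
    return result


def run_morph(
    profile: Profile = SCALED_PROFILE,
    seed: int = 0,
    base: NetworkModel | None = None,
    duration_each: float = 600.0,
    stages: tuple[float, ...] = MORPH_STAGES,
) -> ProtocolResult:
    """Joint training in the 62 cm square (morph stage 0) and radius-39 cm
    circle (stage 1), 10 min each; sampling across the morph stages."""
    for t in stages:
        if not 0.0 <= t <= 1.0:
            raise ValueError("morph parameter outside [0, 1]")
    base = base if base is not None else pretrain_base(profile, seed)

    def stage_maze(t):
        return make_standard_arena(
            "morph_stage", [t], wall_height=LOOK_OVER_HEIGHT, background="panorama",
            circle_segments=profile.circle_segments,
        )

    square, circle = stage_maze(0.0), stage_maze(1.0)
    beh = BehaviorSpec(mode="forage", wall_margin=profile.wall_margin)
    streams = []
    for name, maze in (("square", square), ("circle", circle)):
        traj = forage(maze, beh, duration_each, profile.dt, profile.speed,
                      rng=substream(seed, f"traj_{name}"))
        streams.append(render_stream(maze, traj, profile.camera))
    net = _train(base, streams, profile, seed)

    cfg = RunConfig(protocol="morph", profile=profile.name, seed=seed,
                    overrides={"duration_each": duration_each,
                               "stages": list(stages)})
    result = ProtocolResult(config=cfg, network=net)

    stage_peaks = {}
    for t in stages:
        maze = stage_maze(t)
        by_dir, averaged, report = directional_report(net, maze, profile)
        _store_directional(result, f"stage{t:g}", by_dir, averaged)
        result.reports[f"stage{t:g}"] = report
        stage_peaks[t] = report.per_cell_peak
    result.extras["stage_peaks"] = stage_peaks
    return result


def run_stretch(
    profile: Profile = SCALED_PROFILE,
    seed: int = 0,
    base: NetworkModel | None = None,
    duration: float = 600.0,
    variants: tuple[tuple[float, float], ...] = ((120, 60), (60, 120),
                                                 (60, 60), (120, 120)),
) -> ProtocolResult:
    """Training in a 120x60 cm look-over rectangle for 10 min; sampling in
    the familiar arena and its scaled variants."""
    base = base if base is not None else pretrain_base(profile, seed)
    familiar = make_standard_arena("rectangle", [120.0, 60.0],
                                   wall_height=LOOK_OVER_HEIGHT,
                                   background="panorama")
    beh = BehaviorSpec(mode="forage", wall_margin=profile.wall_margin)
    traj = forage(familiar, beh, duration, profile.dt, profile.speed,
                  rng=substream(seed, "traj"))
    frames = render_stream(familiar, traj, profile.camera)
    net = _train(base, frames, profile, seed)

    cfg = RunConfig(protocol="stretch", profile=profile.name, seed=seed,
                    overrides={"duration": duration, "variants": list(map(list, variants))})
    result = ProtocolResult(config=cfg, network=net)

    for (w, h) in variants:
        maze = make_standard_arena("rectangle", [float(w), float(h)],
                                   wall_height=LOOK_OVER_HEIGHT,
                                   background="panorama")
        by_dir, averaged, report = directional_report(net, maze, profile)
        name = f"{w:g}x{h:g}"
        _store_directional(result, name, by_dir, averaged)
        result.reports[name] = report
    return result


PROTOCOLS = {
    "development_box": lambda **kw: run_development(variant="box", **kw),
    "development_cylinder": lambda **kw: run_development(variant="cylinder", **kw),
    "cue_rotation": run_cue_rotation,
    "cue_removal": run_cue_removal,
    "linear_track": run_linear_track,
    "rhombus": run_rhombus,
    "morph": run_morph,
    "stretch": run_stretch,
}
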