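"""Cross-cutting engineering: run profiles, configuration, deterministic
seeding, persistence and plotting.

A *profile* bundles every resolution-dependent constant: the full profile
reproduces the published network (320x40 frames, 32 channels) and takes
hours to train; the scaled profile shrinks the frames and channel counts so
that every protocol completes in minutes on one CPU while keeping the
32-cell output layer and all arena geometries, durations and behavioural
parameters identical.

A single run seed fans out into named substreams (trajectory generation,
patch subsampling, ICA initialisation, spike emulation, ...) so individual
stages can be re-run independently and still reproduce bitwise.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import yaml

from .hierarchy import (
    FULL_ARCH,
    SCALED_ARCH,
    NetworkArch,
    NetworkModel,
    SfaNode,
)
from .renderer import CameraModel
from .sfa import IcaModel, SfaModel

__all__ = [
    "Profile",
    "FULL_PROFILE",
    "SCALED_PROFILE",
    "get_profile",
    "RunConfig",
    "substream_seed",
    "substream",
    "save_network",
    "load_network",
    "save_run",
    "load_run",
    "plot_panel",
    "spike_pipeline_panel",
]


@dataclass(frozen=True)
class Profile:
    name: str
    arch: NetworkArch
    camera: CameraModel
    dt: float  # s per behaviour/frame step
    speed: float = 20.0  # cm/s, constant
    circle_segments: int = 360
    map_resolution: float = 1.0  # cm/pixel for dense sampling maps
    bin_size: float = 3.0  # cm, spike-map bins
    kernel_width: float = 3.0  # cm, Gaussian smoothing sigma
    generic_frames: int = 100_000
    wall_margin: float = 5.0


FULL_PROFILE = Profile(
    name="full",
    arch=FULL_ARCH,
    camera=CameraModel(n_columns=320, n_rows=40),
    dt=0.05,
)

SCALED_PROFILE = Profile(
    name="scaled",
    arch=SCALED_ARCH,
    camera=CameraModel(n_columns=160, n_rows=24),
    dt=0.05,
    circle_segments=180,
    map_resolution=3.0,
    generic_frames=10_000,
)


def get_profile(name: str) -> Profile:
    try:
        return {"full": FULL_PROFILE, "scaled": SCALED_PROFILE}[name]
    except KeyError:
        raise ValueError(f"unknown profile {name!r}") from None


# ---------------------------------------------------------------------------
# seeding


def substream_seed(seed: int, name: str) -> int:
    """Deterministic child seed (< 2**31) for a named random substream."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(seed, name))


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything needed to reproduce a protocol run."""

    protocol: str
    profile: str = "scaled"
    seed: int = 0
    overrides: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# model persistence (HDF5)


def _save_sfa(g: h5py.Group, m: SfaModel) -> None:
    g.attrs["input_dim"] = m.input_dim
    g.attrs["expansion"] = m.expansion
    g.attrs["dt"] = m.dt
    g.create_dataset("mean", data=m.mean_vector)
    g.create_dataset("projection", data=m.projection)
    g.create_dataset("delta", data=m.delta_values)


def _load_sfa(g: h5py.Group) -> SfaModel:
    return SfaModel(
        input_dim=int(g.attrs["input_dim"]),
        expansion=str(g.attrs["expansion"]),
        mean_vector=g["mean"][:],
        projection=g["projection"][:],
        delta_values=g["delta"][:],
        dt=float(g.attrs["dt"]),
    )


def _save_node(g: h5py.Group, node: SfaNode) -> None:
    if node.reduce is not None:
        _save_sfa(g.create_group("reduce"), node.reduce)
    _save_sfa(g.create_group("main"), node.main)


def _load_node(g: h5py.Group) -> SfaNode:
    reduce = _load_sfa(g["reduce"]) if "reduce" in g else None
    return SfaNode(reduce=reduce, main=_load_sfa(g["main"]))


def save_network(path, net: NetworkModel) -> None:
    with h5py.File(path, "w") as f:
        a = f.create_group("arch")
        for k, v in asdict(net.arch).items():
            a.attrs[k] = v
        for name, node in (("layer1", net.layer1), ("layer2", net.layer2),
                           ("layer3", net.layer3)):
            if node is not None:
                _save_node(f.create_group(name), node)
        if net.ica is not None:
            g = f.create_group("ica")
            g.attrs["input_dim"] = net.ica.input_dim
            g.attrs["n_components"] = net.ica.n_components
            g.attrs["converged"] = net.ica.converged
            g.create_dataset("mean", data=net.ica.mean_vector)
            g.create_dataset("unmixing", data=net.ica.unmixing)
        f.attrs["meta"] = json.dumps(net.meta)


def load_network(path) -> NetworkModel:
    with h5py.File(path, "r") as f:
        kw = {k: v for k, v in f["arch"].attrs.items()}
        for key in ("frame_shape", "rf1", "rf2"):
            kw[key] = tuple(int(x) for x in kw[key])
        for key in ("channels", "reduce_dim", "layer3_out", "ica_out", "max_patches"):
            kw[key] = int(kw[key])
        net = NetworkModel(arch=NetworkArch(**kw))
        for name in ("layer1", "layer2", "layer3"):
            if name in f:
                setattr(net, name, _load_node(f[name]))
        if "ica" in f:
            g = f["ica"]
            net.ica = IcaModel(
                input_dim=int(g.attrs["input_dim"]),
                mean_vector=g["mean"][:],
                unmixing=g["unmixing"][:],
                n_components=int(g.attrs["n_components"]),
                converged=bool(g.attrs["converged"]),
            )
        net.meta = json.loads(f.attrs.get("meta", "{}"))
    return net


# ---------------------------------------------------------------------------
# run persistence


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def save_run(result, out_dir) -> str:
    """Persist a ProtocolResult; returns the manifest path.

    Layout: network.h5, maps.h5 (one group per variant/direction, one
    dataset pair per cell), reports/*.csv, config.yaml, manifest.json with
    per-file digests for corruption detection.
    """
    os.makedirs(out_dir, exist_ok=True)
    files = {}

    net_path = os.path.join(out_dir, "network.h5")
    save_network(net_path, result.network)
    files["network.h5"] = _sha256(net_path)

    maps_path = os.path.join(out_dir, "maps.h5")
    with h5py.File(maps_path, "w") as f:
        for (variant, direction), maps in result.maps.items():
            g = f.create_group(f"{variant}/{direction}")
            g.attrs["resolution"] = maps[0].resolution
            g.attrs["origin"] = maps[0].origin
            g.create_dataset("valid", data=maps[0].valid)
            g.create_dataset("values", data=np.stack([m.values for m in maps]))
    files["maps.h5"] = _sha256(maps_path)

    rep_dir = os.path.join(out_dir, "reports")
    os.makedirs(rep_dir, exist_ok=True)
    for variant, report in result.reports.items():
        p = os.path.join(rep_dir, f"{variant}.csv")
        report.to_csv(p)
        files[f"reports/{variant}.csv"] = _sha256(p)

    cfg_path = os.path.join(out_dir, "config.yaml")
    with open(cfg_path, "w") as fh:
        fh.write(result.config.to_yaml())
    files["config.yaml"] = _sha256(cfg_path)

    manifest = {
        "config_hash": result.config.config_hash,
        "seed": result.config.seed,
        "files": files,
    }
    man_path = os.path.join(out_dir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return man_path


def load_run(out_dir):
    """Load a saved run, verifying file digests (raises on corruption)."""
    from .protocols import ProtocolResult
    from .ratemaps import RateMap

    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    for rel, digest in manifest["files"].items():
        actual = _sha256(os.path.join(out_dir, rel))
        if actual != digest:
            raise ValueError(f"digest mismatch for {rel}: file corrupted")

    with open(os.path.join(out_dir, "config.yaml")) as fh:
        config = RunConfig.from_yaml(fh.read())
    network = load_network(os.path.join(out_dir, "network.h5"))

    maps = {}
    with h5py.File(os.path.join(out_dir, "maps.h5"), "r") as f:
        def visit(variant, direction, g):
            valid = g["valid"][:].astype(bool)
            values = g["values"][:]
            res = float(g.attrs["resolution"])
            origin = tuple(float(x) for x in g.attrs["origin"])
            maps[(variant, direction)] = [
                RateMap(values[c], valid.copy(), res, origin, c, direction)
                for c in range(values.shape[0])
            ]
        for variant in f:
            for direction in f[variant]:
                visit(variant, direction, f[variant][direction])

    reports = {}
    rep_dir = os.path.join(out_dir, "reports")
    if os.path.isdir(rep_dir):
        for fn in sorted(os.listdir(rep_dir)):
            if not fn.endswith(".csv"):
                continue
            rows = np.genfromtxt(os.path.join(rep_dir, fn), delimiter=",",
                                 skip_header=1)
            rows = np.atleast_2d(rows)
            from .metrics import ConsistencyReport
            reports[fn[:-4]] = ConsistencyReport(
                per_cell_directional=rows[:, 1],
                per_cell_field_count=rows[:, 2].astype(int),
                per_cell_peak=rows[:, 3],
            )
    return ProtocolResult(config=config, network=network, maps=maps,
                          reports=reports, extras={})


# ---------------------------------------------------------------------------
# plotting


def plot_panel(maps, path, n_cols: int = 8, titles=None) -> None:
    """Jet-scale panel of ratemaps; invalid pixels rendered as background
    (white), never as low activity; the peak value is annotated per panel."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not maps:
        raise ValueError("no maps to plot")
    n = len(maps)
    n_rows = int(np.ceil(n / n_cols))
    cmap = plt.get_cmap("jet").copy()
    cmap.set_bad("white")
    fig, axes = plt.subplots(n_rows, n_cols, figsize=(2 * n_cols, 2 * n_rows),
                             squeeze=False)
    for i, m in enumerate(maps):
        ax = axes[i // n_cols][i % n_cols]
        vals = np.where(m.valid, m.values, np.nan)
        ax.imshow(vals, cmap=cmap, origin="lower", interpolation="nearest")
        peak = m.peak
        label = titles[i] if titles else f"cell {m.cell_id}"
        ax.set_title(f"{label}  peak {peak:.2f}" if np.isfinite(peak) else label,
                     fontsize=7)
        ax.axis("off")
    for j in range(n, n_rows * n_cols):
        axes[j // n_cols][j % n_cols].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def spike_pipeline_panel(spikes, traj, binned, smoothed, path) -> None:
    """Three-column view of the spike pipeline for one cell: spikes on the
    trajectory, accumulated bin counts, smoothed ratemap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cmap = plt.get_cmap("jet").copy()
    cmap.set_bad("white")
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    axes[0].plot(traj.positions[:, 0], traj.positions[:, 1], lw=0.3, color="0.7")
    if len(spikes.spike_positions):
        axes[0].plot(spikes.spike_positions[:, 0], spikes.spike_positions[:, 1],
                     ".", ms=2, color="red")
    axes[0].set_aspect("equal")
    axes[0].set_title("spikes on trajectory", fontsize=8)
    for ax, m, title in ((axes[1], binned, "binned"), (axes[2], smoothed, "smoothed")):
        vals = np.where(m.valid, m.values, np.nan)
        ax.imshow(vals, cmap=cmap, origin="lower", interpolation="nearest")
        ax.set_title(f"{title}  peak {m.peak:.2f}", fontsize=8)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
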