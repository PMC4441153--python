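"""Four-layer hierarchical SFA network.

Layer 1 is a grid of clone SFA nodes scanning the raw frames through small
receptive fields that overlap neighbours by half their size; layer 2 is a
second, coarser clone grid over layer-1 feature maps; layer 3 is a single
SFA node integrating every layer-2 channel; layer 4 is a single ICA node
performing sparse coding on the layer-3 slow features.  At the full
resolution (320x40 frames, 10x8-pixel fields) the clone grids come out as
63x9 and, with 14x6-node fields, 8x2.

Clone nodes share one weight set: a single SFA model is fitted on training
patches pooled across every receptive-field position (the input statistics
are assumed stationary over the visual field) and then replicated across
the grid for inference.

Every SFA node first reduces its input linearly (by linear SFA) to
``reduce_dim`` dimensions before the quadratic expansion; without this the
upper nodes' raw input dimensionalities (e.g. 14 x 6 x 32 = 2688) would be
far too large to expand.  The reduction dimension is the main capacity
knob of the network.

Training is staged: *generic* pretraining fits layers 1-2 on streams from
several unrelated mazes and freezes them; *experiment* training then fits
layers 3-4 on the visual stream of the actual experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import sfa as _sfa
from .sfa import (
    IcaModel,
    MomentAccumulator,
    SfaModel,
    SignalBatch,
    expanded_dim,
    fit_ica,
    fit_sfa_from_moments,
    quadratic_expand,
)

__all__ = [
    "NetworkArch",
    "FULL_ARCH",
    "SCALED_ARCH",
    "SfaNode",
    "NetworkModel",
    "grid_layout",
    "train_clone_layer",
    "generic_pretrain",
    "experiment_train",
    "forward",
    "forward_stream",
]


def _axis_nodes(extent: int, rf: int, axis: str) -> int:
    if rf == extent:
        return 1
    if rf % 2:
        raise ValueError(f"{axis} axis: receptive field {rf} must be even")
    if rf > extent or (extent - rf) % (rf // 2):
        raise ValueError(
            f"{axis} axis: extent {extent} does not tile with receptive "
            f"field {rf} at 50% overlap"
        )
    return (extent - rf) // (rf // 2) + 1


def grid_layout(input_extent: tuple[int, int], rf: tuple[int, int]) -> tuple[int, int]:
    """Clone-grid shape for a (width, height) extent tiled by (rw, rh)
    receptive fields overlapping 50%: nodes per axis = (extent - rf)/(rf/2) + 1."""
    nx = _axis_nodes(input_extent[0], rf[0], "x")
    ny = _axis_nodes(input_extent[1], rf[1], "y")
    return nx, ny


@dataclass(frozen=True)
class NetworkArch:
    """Architecture hyperparameters (one frozen set per profile)."""

    frame_shape: tuple[int, int]  # (rows, cols)
    rf1: tuple[int, int] = (10, 8)  # (rw, rh) in pixels
    rf2: tuple[int, int] = (14, 6)  # (rw, rh) in layer-1 nodes
    channels: int = 32
    reduce_dim: int = 48
    layer3_out: int = 32
    ica_out: int = 32
    max_patches: int = 200_000
    #: covariance ridge (fraction of mean variance) emulating additive
    #: observation noise; guards the fits against trajectory memorisation
    shrinkage: float = 0.01

    @property
    def grid1(self) -> tuple[int, int]:
        rows, cols = self.frame_shape
        return grid_layout((cols, rows), self.rf1)

    @property
    def grid2(self) -> tuple[int, int]:
        return grid_layout(self.grid1, self.rf2)


#: paper-scale architecture: 320x40 frames -> 63x9 -> 8x2 -> 1 -> ICA(32)
FULL_ARCH = NetworkArch(frame_shape=(40, 320))

#: desk-scale architecture: 160x24 frames (2 deg/column), 16 channels,
#: 15x5 and 4x4 clone grids, same 32-cell output layer as the full network
SCALED_ARCH = NetworkArch(
    frame_shape=(24, 160),
    rf1=(20, 8),
    rf2=(6, 2),
    channels=16,
    reduce_dim=24,
)


# ---------------------------------------------------------------------------
# patch plumbing


def _patch_view(arr: np.ndarray, rf: tuple[int, int]) -> np.ndarray:
    """Strided view of all 50%-overlap patches.

    ``arr`` is (T, H, W) or (T, H, W, ch); the result is
    (T, ny, nx, rh, rw[, ch]) without copying.
    """
    rw, rh = rf
    sy, sx = max(rh // 2, 1), max(rw // 2, 1)
    if arr.ndim == 3:
        v = sliding_window_view(arr, (rh, rw), axis=(1, 2))
        return v[:, ::sy, ::sx]
    v = sliding_window_view(arr, (rh, rw), axis=(1, 2))  # (T, Hy, Wx, ch, rh, rw)
    v = v[:, ::sy, ::sx]
    return np.moveaxis(v, 3, 5)  # (T, ny, nx, rh, rw, ch)


def _flat_patches(view: np.ndarray, t0: int, t1: int) -> np.ndarray:
    """(m, P, d) float64 copy of a time slice of a patch view."""
    block = np.asarray(view[t0:t1], dtype=float)
    m = block.shape[0]
    p = block.shape[1] * block.shape[2]
    return block.reshape(m, p, -1)


@dataclass
class SfaNode:
    """Composite SFA node: linear slow-feature reduction, then quadratic SFA."""

    reduce: SfaModel | None
    main: SfaModel

    @property
    def input_dim(self) -> int:
        return self.reduce.input_dim if self.reduce is not None else self.main.input_dim

    @property
    def n_outputs(self) -> int:
        return self.main.n_outputs

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.reduce is not None:
            x = self.reduce.transform(x)
        return self.main.transform(x)


def _fit_sfa_node(
    streams: Sequence[np.ndarray],
    rf: tuple[int, int],
    out_channels: int,
    reduce_dim: int,
    dt: float,
    max_patches: int,
    rng: np.random.Generator,
    shrinkage: float = 0.0,
) -> SfaNode:
    """Fit one clone node on patches pooled over grid positions and streams.

    Temporal derivatives are taken between consecutive frames at the same
    grid position, never across stream boundaries.  The quadratic stage
    subsamples patches down to ``max_patches`` to bound memory and time.
    """
    views = [_patch_view(s, rf) for s in streams]
    d = int(np.prod(views[0].shape[3:]))
    n_pos = views[0].shape[1] * views[0].shape[2]
    total = sum(v.shape[0] for v in views) * n_pos

    # pass 1: linear reduction moments over every patch
    acc = MomentAccumulator(d)
    chunk = max(2, int(4_000_000 // max(n_pos * d, 1)))
    for v in views:
        t = 0
        prev_tail = None
        while t < v.shape[0]:
            t1 = min(v.shape[0], t + chunk)
            block = _flat_patches(v, t, t1)  # (m, P, d)
            acc.add_samples(block.reshape(-1, d))
            if prev_tail is not None:
                acc.add_derivatives((block[0] - prev_tail) / dt)
            if t1 - t > 1:
                acc.add_derivatives((np.diff(block, axis=0) / dt).reshape(-1, d))
            prev_tail = block[-1]
            t = t1
    mean, cov, dcov = acc.moments()
    w = np.linalg.eigvalsh(cov)
    rank = int((w > _sfa.RANK_RTOL * w[-1]).sum())
    r = min(reduce_dim, rank)
    reduce = fit_sfa_from_moments(mean, cov, dcov, r, d, "linear", dt,
                                  shrinkage=shrinkage)

    # pass 2: quadratic moments on reduced patches, subsampled
    m_dim = expanded_dim(r)
    q = min(1.0, max_patches / max(total, 1))
    acc2 = MomentAccumulator(m_dim)
    chunk = max(2, int(4_000_000 // max(n_pos * m_dim, 1)))
    for v in views:
        t = 0
        prev_tail = None
        while t < v.shape[0]:
            t1 = min(v.shape[0], t + chunk)
            red = reduce.transform(_flat_patches(v, t, t1))  # (m, P, r)
            z = quadratic_expand(red)
            flat = z.reshape(-1, m_dim)
            if q < 1.0:
                sel = rng.random(len(flat)) < q
                acc2.add_samples(flat[sel])
            else:
                acc2.add_samples(flat)
            dz = np.diff(z, axis=0)
            if prev_tail is not None:
                dz = np.concatenate([(z[0] - prev_tail)[None], dz], axis=0)
            if len(dz):
                dflat = dz.reshape(-1, m_dim) / dt
                if q < 1.0:
                    sel = rng.random(len(dflat)) < q
                    dflat = dflat[sel]
                acc2.add_derivatives(dflat)
            prev_tail = z[-1]
            t = t1
    mean2, cov2, dcov2 = acc2.moments()
    w2 = np.linalg.eigvalsh(cov2)
    rank2 = int((w2 > _sfa.RANK_RTOL * w2[-1]).sum())
    k = min(out_channels, rank2)
    if k < out_channels:
        raise ValueError(
            f"insufficient rank ({rank2}) for {out_channels} output channels"
        )
    main = fit_sfa_from_moments(mean2, cov2, dcov2, k, r, "quadratic", dt,
                                shrinkage=shrinkage)
    return SfaNode(reduce=reduce, main=main)


def train_clone_layer(
    streams: Sequence[np.ndarray] | np.ndarray,
    rf: tuple[int, int],
    out_channels: int,
    reduce_dim: int,
    dt: float,
    max_patches: int = 200_000,
    rng: np.random.Generator | None = None,
    shrinkage: float = 0.0,
) -> SfaNode:
    """Train one shared clone node for a layer (see ``_fit_sfa_node``)."""
    if isinstance(streams, np.ndarray):
        streams = [streams]
    if not streams or any(len(s) < 2 for s in streams):
        raise ValueError("need non-empty streams with at least two frames")
    rng = rng if rng is not None else np.random.default_rng(0)
    return _fit_sfa_node(list(streams), rf, out_channels, reduce_dim, dt,
                         max_patches, rng, shrinkage)


def apply_clone_layer(node: SfaNode, stream: np.ndarray, rf: tuple[int, int]) -> np.ndarray:
    """Run the (cloned) node over every grid position: (T, ny, nx, ch)."""
    view = _patch_view(stream, rf)
    t_total, ny, nx = view.shape[:3]
    d = int(np.prod(view.shape[3:]))
    out = np.empty((t_total, ny, nx, node.n_outputs), dtype=np.float32)
    # chunk by the node's *expanded* width — the quadratic expansion inside
    # transform dominates the transient footprint
    width = max(ny * nx * max(d, expanded_dim(node.main.input_dim)), 1)
    chunk = max(1, int(3_000_000 // width))
    for t0 in range(0, t_total, chunk):
        t1 = min(t_total, t0 + chunk)
        block = _flat_patches(view, t0, t1)
        out[t0:t1] = node.transform(block).reshape(t1 - t0, ny, nx, -1)
    return out


# ---------------------------------------------------------------------------
# the full network


@dataclass
class NetworkModel:
    """The 4-layer model: clone SFA grids, integrating SFA node, ICA node."""

    arch: NetworkArch
    layer1: SfaNode | None = None
    layer2: SfaNode | None = None
    layer3: SfaNode | None = None
    ica: IcaModel | None = None
    meta: dict = field(default_factory=dict)

    @property
    def pretrained(self) -> bool:
        return self.layer1 is not None and self.layer2 is not None

    @property
    def trained(self) -> bool:
        return self.pretrained and self.layer3 is not None and self.ica is not None

    @property
    def trained_flags(self) -> tuple[bool, bool, bool, bool]:
        return (
            self.layer1 is not None,
            self.layer2 is not None,
            self.layer3 is not None,
            self.ica is not None,
        )


def _check_frames(arch: NetworkArch, frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.shape[1:] != arch.frame_shape:
        raise ValueError(
            f"expected frames of shape {arch.frame_shape}, got {frames.shape[1:]}"
        )
    return frames


def features_layer2(net: NetworkModel, frames: np.ndarray) -> np.ndarray:
    """Propagate frames through the frozen lower layers: (T, ny2, nx2, ch)."""
    if not net.pretrained:
        raise ValueError("lower layers are untrained")
    frames = _check_frames(net.arch, frames)
    f1 = apply_clone_layer(net.layer1, frames, net.arch.rf1)
    return apply_clone_layer(net.layer2, f1, net.arch.rf2)


def generic_pretrain(
    net: NetworkModel,
    generic_streams: Sequence[np.ndarray],
    dt: float,
    seed: int = 0,
) -> NetworkModel:
    """Fit and freeze layers 1-2 on streams from several generic mazes;
    layers 3-4 are left untrained."""
    if len(generic_streams) < 2:
        raise ValueError("generic pretraining needs streams from >= 2 mazes")
    arch = net.arch
    streams = [_check_frames(arch, s) for s in generic_streams]
    rng = np.random.default_rng(seed)
    net.layer1 = train_clone_layer(
        streams, arch.rf1, arch.channels, arch.reduce_dim, dt, arch.max_patches,
        rng, arch.shrinkage,
    )
    f1 = [apply_clone_layer(net.layer1, s, arch.rf1) for s in streams]
    net.layer2 = train_clone_layer(
        f1, arch.rf2, arch.channels, arch.reduce_dim, dt, arch.max_patches,
        rng, arch.shrinkage,
    )
    net.layer3 = None
    net.ica = None
    return net


def experiment_train(
    net: NetworkModel,
    frames: np.ndarray | Sequence[np.ndarray],
    dt: float,
    seed: int = 0,
) -> NetworkModel:
    """Fit layer 3 (SFA) and layer 4 (ICA) on an experiment stream.

    ``frames`` may be a list of streams (e.g. the two sessions of a
    two-arena protocol); temporal derivatives are never taken across
    stream boundaries.  Layers 1-2 must already be pretrained and are
    never modified.
    """
    if not net.pretrained:
        raise ValueError("generic pretraining required before experiment training")
    arch = net.arch
    streams = [frames] if isinstance(frames, np.ndarray) else list(frames)
    flats = []
    for s in streams:
        f2 = features_layer2(net, s)
        flats.append(f2.reshape(f2.shape[0], 1, 1, -1))  # one full-extent patch/frame
    rng = np.random.default_rng(seed)
    net.layer3 = _fit_sfa_node(
        flats, (1, 1), arch.layer3_out, arch.reduce_dim, dt, arch.max_patches,
        rng, arch.shrinkage,
    )
    y3 = np.concatenate(
        [net.layer3.transform(fl.reshape(fl.shape[0], -1)) for fl in flats], axis=0
    )
    net.ica = fit_ica(SignalBatch(y3, dt), arch.ica_out, seed=seed)
    return net


def forward_stream(net: NetworkModel, frames: np.ndarray) -> np.ndarray:
    """Propagate frames through the trained network: (T, 32) activities."""
    if not net.trained:
        raise ValueError("network is not fully trained")
    f2 = features_layer2(net, frames)
    y3 = net.layer3.transform(f2.reshape(f2.shape[0], -1))
    return net.ica.transform(y3)


def forward(net: NetworkModel, frame: np.ndarray) -> np.ndarray:
    """Activity vector (one value per output cell) for a single frame."""
    return forward_stream(net, np.asarray(frame)[None])[0]
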