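"""Quantitative analyses of ratemaps.

Two population measures are computed per cell:

* directional consistency — the mean Pearson correlation between each of
  the eight fixed-head-direction maps and their pixelwise average; 1 means
  firing is invariant to the direction the agent faces, values near 0 mean
  strongly directional firing;
* spatial consistency — the number of place fields: connected regions of
  activity above 50% of the cell's peak, after discarding regions of
  25 cm² or less.

Also here: the silent / unidirectional / bidirectional classification used
for track protocols, and automatic one-to-one matching of cells between two
independently trained networks (the ICA layer permutes outputs arbitrarily,
so cells must be paired by map similarity before any across-network
comparison).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import label as cc_label
from scipy.optimize import linear_sum_assignment

from .ratemaps import RateMap

__all__ = [
    "PlaceField",
    "ConsistencyReport",
    "directional_consistency",
    "segment_fields",
    "classify_track_cell",
    "classify_track_population",
    "match_cells",
    "field_rotation_deg",
]

_STRUCT8 = np.ones((3, 3), dtype=int)
_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class PlaceField:
    """A connected supra-threshold region of a ratemap."""

    pixel_idx: np.ndarray  # (n, 2) array of (iy, ix) pixels
    area_cm2: float
    centroid: tuple[float, float]  # cm, arena coordinates
    peak_value: float

    @property
    def area_pixels(self) -> int:
        return len(self.pixel_idx)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r; a zero-variance input contributes 0 (degenerate map)."""
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt((a * a).sum()), np.sqrt((b * b).sum())
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float((a * b).sum() / (na * nb))


def directional_consistency(maps8: list[RateMap], avg: RateMap) -> float:
    """Mean correlation of the fixed-direction maps with their average."""
    mask = avg.valid
    if not mask.any():
        raise ValueError("empty valid mask")
    ref = avg.values[mask]
    rs = []
    for m in maps8:
        if not np.array_equal(m.valid, mask):
            raise ValueError("directional maps must share the valid mask")
        rs.append(_pearson(m.values[mask], ref))
    return float(np.mean(rs))


def segment_fields(
    rmap: RateMap,
    threshold_fraction: float = 0.5,
    min_area_cm2: float = 25.0,
    connectivity: int = 8,
    peak: float | None = None,
) -> list[PlaceField]:
    """Connected regions above ``threshold_fraction`` of the cell's peak.

    ``peak`` is the cell's maximum activity; it defaults to this map's own
    peak, but callers comparing several maps of one cell on a common scale
    (e.g. the two traversal directions of a track) pass the cell-wide
    maximum so a weak condition cannot manufacture fields of its own.
    Negative activity is clipped at zero first (fields are positive bumps
    under the sign convention of the ICA layer); regions whose area is
    ``min_area_cm2`` or less are discarded.  Fields come sorted by
    descending area.
    """
    vals = np.where(rmap.valid, np.clip(rmap.values, 0.0, None), 0.0)
    peak = vals.max(initial=0.0) if peak is None else peak
    if peak <= 0.0:
        return []
    above = (vals > threshold_fraction * peak) & rmap.valid
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    labels, n = cc_label(above, structure=struct)
    px_area = rmap.resolution**2
    fields = []
    x0, y0 = rmap.origin
    for lbl in range(1, n + 1):
        iy, ix = np.nonzero(labels == lbl)
        area = len(iy) * px_area
        if area <= min_area_cm2:
            continue
        weights = vals[iy, ix]
        cx = x0 + (ix + 0.5) @ weights / weights.sum() * rmap.resolution
        cy = y0 + (iy + 0.5) @ weights / weights.sum() * rmap.resolution
        fields.append(
            PlaceField(np.column_stack([iy, ix]), area, (float(cx), float(cy)),
                       float(weights.max()))
        )
    fields.sort(key=lambda f: -f.area_cm2)
    return fields


def classify_track_cell(
    map_dir_a: RateMap,
    map_dir_b: RateMap,
    population_median_peak: float,
    activity_floor: float = 0.1,
    min_area_cm2: float = 25.0,
) -> str:
    """Silent / unidirectional / bidirectional classification of one cell
    from its two opposite-traversal maps.

    Both maps must share the cell's rate scale (spike probabilities
    normalised by the cell's trajectory-wide peak), so segmentation uses
    the cell-wide maximum.  Each direction is rated *clear* (has a
    segmented field), *active* (crosses half the cell's peak but forms no
    field — significant yet unstructured activity), or *none* (little to
    no activity: never reaches the segmentation threshold, or below
    ``activity_floor`` times the population median peak).  The labels then
    follow the experimental convention: unidirectional means a clear field
    in exactly one direction with little to no activity in the other;
    a clear field accompanied by any significant activity the other way
    counts as bidirectional; no clear field at all counts as silent.
    """
    floor = activity_floor * population_median_peak

    def peak_of(m: RateMap) -> float:
        p = m.peak
        return p if np.isfinite(p) else 0.0

    cell_peak = max(peak_of(map_dir_a), peak_of(map_dir_b))

    def state(m: RateMap) -> str:
        p = peak_of(m)
        if cell_peak <= 0.0 or p < floor:
            return "none"
        if segment_fields(m, min_area_cm2=min_area_cm2, peak=cell_peak):
            return "clear"
        return "active" if p >= 0.5 * cell_peak else "none"

    sa, sb = state(map_dir_a), state(map_dir_b)
    if "clear" not in (sa, sb):
        return "silent"
    if (sa == "clear" and sb == "none") or (sb == "clear" and sa == "none"):
        return "unidirectional"
    return "bidirectional"


def classify_track_population(
    maps_dir_a: list[RateMap],
    maps_dir_b: list[RateMap],
    activity_floor: float = 0.1,
    min_area_cm2: float = 25.0,
) -> list[str]:
    """Classify all cells, deriving the peak floor from the population."""
    peaks = []
    for ma, mb in zip(maps_dir_a, maps_dir_b):
        pa, pb = ma.peak, mb.peak
        peaks.append(max(pa if np.isfinite(pa) else 0.0, pb if np.isfinite(pb) else 0.0))
    median_peak = float(np.median(peaks))
    return [
        classify_track_cell(ma, mb, median_peak, activity_floor, min_area_cm2)
        for ma, mb in zip(maps_dir_a, maps_dir_b)
    ]


def match_cells(netA_maps: list[RateMap], netB_maps: list[RateMap]):
    """Optimal one-to-one pairing of cells across two networks.

    Maximises the total absolute map correlation (automating by-hand signal
    matching); returns ``(permutation, scores)`` where ``permutation[i]`` is
    the index of the B-cell paired with A-cell i.
    """
    if len(netA_maps) != len(netB_maps):
        raise ValueError("population sizes differ")
    n = len(netA_maps)
    corr = np.zeros((n, n))
    for i, ma in enumerate(netA_maps):
        mask = ma.valid
        for j, mb in enumerate(netB_maps):
            if mb.values.shape != ma.values.shape:
                raise ValueError("maps have different grids")
            m = mask & mb.valid
            if not m.any():
                continue
            corr[i, j] = abs(_pearson(ma.values[m], mb.values[m]))
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(n, dtype=int)
    perm[rows] = cols
    return perm, corr[rows, cols]


def field_rotation_deg(
    centroid_before: tuple[float, float],
    centroid_after: tuple[float, float],
    center: tuple[float, float] = (0.0, 0.0),
) -> float:
    """CCW rotation (degrees, in (-180, 180]) of a field centroid about the
    arena centre — used to quantify cue-following after cue rotation."""
    a = np.arctan2(centroid_before[1] - center[1], centroid_before[0] - center[0])
    b = np.arctan2(centroid_after[1] - center[1], centroid_after[0] - center[0])
    d = np.degrees(b - a)
    return float((d + 180.0) % 360.0 - 180.0)


@dataclass
class ConsistencyReport:
    """Per-cell directional consistency, field count and peak activity."""

    per_cell_directional: np.ndarray
    per_cell_field_count: np.ndarray
    per_cell_peak: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.per_cell_directional, dtype=float)
        if np.any((d < -1 - 1e-9) | (d > 1 + 1e-9)):
            raise ValueError("correlations must lie in [-1, 1]")
        if np.any(np.asarray(self.per_cell_field_count) < 0):
            raise ValueError("field counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.per_cell_directional)

    def directional_histogram(self, bins=10):
        return np.histogram(self.per_cell_directional, bins=bins, range=(-1.0, 1.0))

    def field_count_histogram(self):
        counts = np.asarray(self.per_cell_field_count)
        top = max(int(counts.max(initial=0)), 1)
        return np.histogram(counts, bins=np.arange(top + 2) - 0.5)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cell_id", "directional_consistency", "field_count", "peak"])
            for i in range(self.n_cells):
                w.writerow([
                    i,
                    f"{self.per_cell_directional[i]:.6f}",
                    int(self.per_cell_field_count[i]),
                    f"{self.per_cell_peak[i]:.6f}",
                ])
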