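"""Interaction and distance analysis on 3D filament networks.

Implements the microtubule "interaction" statistic used for
electron-tomography reconstructions of the spindle midzone: a stretch of
one microtubule lying within a maximum center-to-center distance (default
100 nm) of another microtubule for at least a minimum arc length (default
100 nm).  Each filament is resampled at a uniform arc step, per-sample
distances to the partner filament are computed exactly (point to segment),
maximal in-threshold runs become interactions, and run boundaries are
refined by linear interpolation of the distance profile across the
threshold crossing.

Pairwise filament distances are the exact minimum over all segment pairs;
a 3D grid spatial index accelerates the interaction scan without changing
its result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import UndefinedAngleError
from .filaments import Filament, FilamentNetwork

__all__ = [
    "Interaction",
    "NetworkStats",
    "segment_min_distance",
    "filament_pair_distance",
    "interaction_angle",
    "detect_interactions",
    "nearest_neighbor_distances",
    "network_stats",
    "GridIndex",
    "resample_polyline",
    "point_to_filament_distance",
    "interactions_to_csv",
    "DEFAULT_DISTANCE_BINS",
]

_EPS = 1e-12

#: Upper bin edges (nm) for interaction-distance fractions: 25-100 nm in
#: 5 nm steps, mirroring the red (25 nm) to white (>100 nm) color coding of
#: tomography interaction maps.  An implicit > last-edge bin is appended.
DEFAULT_DISTANCE_BINS: tuple[float, ...] = tuple(float(x) for x in range(25, 105, 5))


# ---------------------------------------------------------------------------
# Elementary geometry
# ---------------------------------------------------------------------------

def _seg_seg_distance(p1, q1, p2, q2):
    """Vectorized exact minimum distance between closed segments.

    All inputs broadcast against each other with a trailing axis of 3.
    Degenerate (point) segments are handled.
    """
    p1, q1, p2, q2 = (np.asarray(x, dtype=float) for x in (p1, q1, p2, q2))
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = (d1 * d1).sum(-1)
    e = (d2 * d2).sum(-1)
    f = (d2 * r).sum(-1)
    c = (d1 * r).sum(-1)
    b = (d1 * d2).sum(-1)
    denom = a * e - b * b

    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > _EPS,
                     np.clip(np.where(denom > _EPS, (b * f - c * e), 0.0)
                             / np.where(denom > _EPS, denom, 1.0), 0.0, 1.0),
                     0.0)
        t = np.where(e > _EPS, (b * s + f) / np.where(e > _EPS, e, 1.0), 0.0)
        out_of_range = (t < 0.0) | (t > 1.0) | (e <= _EPS)
        t = np.clip(t, 0.0, 1.0)
        s_re = np.where(a > _EPS,
                        np.clip((b * t - c) / np.where(a > _EPS, a, 1.0), 0.0, 1.0),
                        0.0)
        s = np.where(out_of_range, s_re, s)
        s = np.where(a > _EPS, s, 0.0)

    c1 = p1 + s[..., None] * d1
    c2 = p2 + t[..., None] * d2
    return np.linalg.norm(c1 - c2, axis=-1)


def segment_min_distance(a_start, a_end, b_start, b_end) -> float:
    """Exact minimum Euclidean distance between two closed 3D segments (nm)."""
    return float(_seg_seg_distance(a_start, a_end, b_start, b_end))


def _point_segments_distance(points: np.ndarray, seg_a: np.ndarray,
                             seg_b: np.ndarray) -> np.ndarray:
    """(P,) min distance from each point to a set of segments."""
    ab = seg_b - seg_a                                    # (S, 3)
    denom = (ab * ab).sum(-1)                             # (S,)
    ap = points[:, None, :] - seg_a[None, :, :]           # (P, S, 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ap * ab[None]).sum(-1) / np.where(denom > _EPS, denom, 1.0)
    t = np.clip(np.where(denom > _EPS, t, 0.0), 0.0, 1.0)
    closest = seg_a[None] + t[..., None] * ab[None]
    return np.linalg.norm(points[:, None, :] - closest, axis=-1).min(axis=1)


def point_to_filament_distance(points: np.ndarray, filament: Filament) -> np.ndarray:
    """Exact distance (nm) from each query point to a filament polyline."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return _point_segments_distance(pts, filament.points[:-1], filament.points[1:])


def filament_pair_distance(f: Filament, g: Filament) -> float:
    """Minimum distance between two filaments: min over all segment pairs."""
    a0, a1 = f.points[:-1], f.points[1:]
    b0, b1 = g.points[:-1], g.points[1:]
    d = _seg_seg_distance(a0[:, None, :], a1[:, None, :],
                          b0[None, :, :], b1[None, :, :])
    return float(d.min())


def interaction_angle(f: Filament, g: Filament, fold: bool = False) -> float:
    """Angle (degrees) between end-to-end lines of two filaments.

    Defined on the lines through start and end points to be robust to local
    distortions of the traces.  0 deg = parallel with the same start->end
    orientation, 180 deg = antiparallel; ``fold=True`` folds to [0, 90] for
    orientation-agnostic summaries.
    """
    try:
        u = f.orientation
        v = g.orientation
    except Exception as exc:
        raise UndefinedAngleError(
            f"filament pair ({f.id}, {g.id}): zero end-to-end vector") from exc
    ang = float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))
    if fold and ang > 90.0:
        ang = 180.0 - ang
    return ang


def resample_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Uniform arc-length resampling.

    Returns ``(arcs, samples)`` where ``arcs`` runs 0, step, 2*step, ...
    and always includes the final arc length.
    """
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    total = u[-1]
    arcs = np.arange(0.0, total, step)
    if total - arcs[-1] > 1e-9:
        arcs = np.append(arcs, total)
    else:
        arcs[-1] = total
    samples = np.column_stack([np.interp(arcs, u, pts[:, k]) for k in range(3)])
    return arcs, samples


# ---------------------------------------------------------------------------
# Spatial index
# ---------------------------------------------------------------------------

class GridIndex:
    """3D uniform-grid spatial hash over filament segments.

    With ``cell >= d_max`` any query within ``d_max`` of a point only needs
    the 27-neighborhood of the point's cell, so results are identical to a
    full scan.
    """

    def __init__(self, network: FilamentNetwork, cell: float):
        if cell <= 0:
            raise ValueError("cell must be > 0")
        self.cell = float(cell)
        self._cells: dict[tuple[int, int, int], list[tuple[int, int]]] = {}
        self._segments: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for f in network:
            a, b = f.points[:-1], f.points[1:]
            self._segments[f.id] = (a, b)
            lo = np.floor(np.minimum(a, b) / cell).astype(int)
            hi = np.floor(np.maximum(a, b) / cell).astype(int)
            for si in range(a.shape[0]):
                for ix in range(lo[si, 0], hi[si, 0] + 1):
                    for iy in range(lo[si, 1], hi[si, 1] + 1):
                        for iz in range(lo[si, 2], hi[si, 2] + 1):
                            self._cells.setdefault((ix, iy, iz), []).append((f.id, si))

    def __len__(self) -> int:
        return len(self._cells)

    def segments_near(self, point: np.ndarray, target_id: int,
                      reach: int = 1) -> np.ndarray:
        """Indices of ``target_id`` segments within ``reach`` cells of
        ``point``'s cell (reach=1 is the 27-neighborhood)."""
        cx, cy, cz = np.floor(np.asarray(point) / self.cell).astype(int)
        found: list[int] = []
        span = range(-reach, reach + 1)
        for dx in span:
            for dy in span:
                for dz in span:
                    for fid, si in self._cells.get((cx + dx, cy + dy, cz + dz), ()):
                        if fid == target_id:
                            found.append(si)
        return np.unique(np.array(found, dtype=int))

    def distance_profile(self, samples: np.ndarray, target_id: int,
                         upper_bound: float) -> np.ndarray:
        """Per-sample distance to the target filament, exact wherever the
        true distance is <= ``upper_bound``; +inf beyond.  A cell smaller
        than the bound just widens the search ring (more cells visited)."""
        a, b = self._segments[target_id]
        reach = max(1, int(np.ceil(upper_bound / self.cell)))
        out = np.full(samples.shape[0], np.inf)
        for i, p in enumerate(samples):
            idx = self.segments_near(p, target_id, reach=reach)
            if idx.size:
                out[i] = _point_segments_distance(p[None, :], a[idx], b[idx])[0]
        # distances found beyond the guarantee radius may be overestimates of
        # segments outside the neighborhood; callers only rely on values
        # <= upper_bound, which are exact
        return out


# ---------------------------------------------------------------------------
# Interaction detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interaction:
    """A contiguous stretch of ``source_id`` within the distance threshold
    of ``target_id``.  Arc positions are on the source filament, nm."""

    source_id: int
    target_id: int
    start_arc: float
    end_arc: float
    length: float
    min_distance: float
    angle: float


def _runs_from_profile(arcs: np.ndarray, d: np.ndarray, d_max: float,
                       l_min: float) -> list[tuple[float, float, float]]:
    """Maximal in-threshold runs of a distance profile.

    Returns ``(start_arc, end_arc, min_distance)`` per retained run; run
    boundaries are refined by linear interpolation between the bracketing
    samples, runs shorter than ``l_min`` are dropped.  A single sample
    beyond the threshold splits a run (no gap bridging).
    """
    inside = d <= d_max
    if not inside.any():
        return []
    idx = np.flatnonzero(inside)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])

    runs = []
    for i0, i1 in zip(starts, ends):
        if i0 == 0:
            start = arcs[0]
        else:
            d_out, d_in = d[i0 - 1], d[i0]
            frac = (d_out - d_max) / (d_out - d_in)
            start = arcs[i0 - 1] + frac * (arcs[i0] - arcs[i0 - 1])
        if i1 == len(arcs) - 1:
            end = arcs[-1]
        else:
            d_out, d_in = d[i1 + 1], d[i1]
            frac = (d_out - d_max) / (d_out - d_in)
            end = arcs[i1 + 1] - frac * (arcs[i1 + 1] - arcs[i1])
        if end - start >= l_min - 1e-9:
            runs.append((float(start), float(end), float(d[i0:i1 + 1].min())))
    return runs


def detect_interactions(network: FilamentNetwork, d_max: float = 100.0,
                        l_min: float = 100.0, resample_step: float = 20.0,
                        use_grid: bool = True, cell: float | None = None,
                        mode: str = "ordered") -> list[Interaction]:
    """Detect microtubule interactions in a filament network.

    For every ordered pair (source, target), the source is resampled at
    ``resample_step`` nm; maximal runs of samples within ``d_max`` nm of the
    target, at least ``l_min`` nm long after boundary interpolation, are
    reported.  No angle restriction is applied.

    ``mode="ordered"`` (default) reports one record per directional run,
    matching a per-microtubule parts bookkeeping; ``mode="symmetric"``
    keeps one direction per unordered pair (the one with the larger total
    run length) for deduplicated counts.
    """
    if d_max <= 0 or resample_step <= 0:
        raise ValueError("d_max and resample_step must be > 0")
    if l_min < 0:
        raise ValueError("l_min must be >= 0")
    if mode not in ("ordered", "symmetric"):
        raise ValueError(f"unknown mode {mode!r}")
    fils = list(network.filaments)
    if len(fils) < 2:
        return []

    resampled = {f.id: resample_polyline(f.points, resample_step) for f in fils}
    boxes = {f.id: (f.points.min(axis=0), f.points.max(axis=0)) for f in fils}
    grid = GridIndex(network, cell=cell or max(d_max, resample_step)) if use_grid else None

    out: list[Interaction] = []
    for src, tgt in itertools.permutations(fils, 2):
        lo_s, hi_s = boxes[src.id]
        lo_t, hi_t = boxes[tgt.id]
        if np.any(lo_s - d_max > hi_t) or np.any(lo_t - d_max > hi_s):
            continue
        arcs, samples = resampled[src.id]
        if grid is not None:
            d = grid.distance_profile(samples, tgt.id, upper_bound=d_max)
            inside = d <= d_max
            if inside.any():
                # exact distances for the out-of-threshold samples bracketing
                # each run, so boundary interpolation matches a full scan
                edge = np.flatnonzero(np.diff(inside.astype(int)) != 0)
                need = np.unique(np.concatenate([edge, edge + 1]))
                need = need[~inside[need]]
                if need.size:
                    d[need] = point_to_filament_distance(samples[need], tgt)
        else:
            d = point_to_filament_distance(samples, tgt)
        runs = _runs_from_profile(arcs, d, d_max, l_min)
        if not runs:
            continue
        ang = interaction_angle(src, tgt)
        for start, end, mind in runs:
            out.append(Interaction(src.id, tgt.id, start, end, end - start, mind, ang))

    if mode == "symmetric":
        out = _symmetric_merge(out)
    return out


def _symmetric_merge(interactions: list[Interaction]) -> list[Interaction]:
    by_pair: dict[tuple[int, int], dict[int, list[Interaction]]] = {}
    for it in interactions:
        key = (min(it.source_id, it.target_id), max(it.source_id, it.target_id))
        by_pair.setdefault(key, {}).setdefault(it.source_id, []).append(it)
    merged: list[Interaction] = []
    for key in sorted(by_pair):
        directions = by_pair[key]
        best = max(
            directions,
            key=lambda sid: (sum(i.length for i in directions[sid]), -sid),
        )
        merged.extend(directions[best])
    return merged


# ---------------------------------------------------------------------------
# Nearest neighbors and summary statistics
# ---------------------------------------------------------------------------

def _box_gap(lo1, hi1, lo2, hi2) -> float:
    gap = np.maximum(0.0, np.maximum(lo2 - hi1, lo1 - hi2))
    return float(np.linalg.norm(gap))


def nearest_neighbor_distances(network: FilamentNetwork) -> pd.DataFrame:
    """Per filament, the closest other filament (exact segment distances).

    Ties are broken toward the smaller filament id.  Bounding-box lower
    bounds prune the exact scan without changing its result.
    """
    fils = list(network.filaments)
    if len(fils) < 2:
        raise ValueError("nearest neighbors need >= 2 filaments")
    boxes = {f.id: (f.points.min(axis=0), f.points.max(axis=0)) for f in fils}
    rows = []
    for f in fils:
        lo_f, hi_f = boxes[f.id]
        order = sorted(
            (g for g in fils if g.id != f.id),
            key=lambda g: (_box_gap(lo_f, hi_f, *boxes[g.id]), g.id),
        )
        best_d, best_id = np.inf, None
        for g in order:
            if _box_gap(lo_f, hi_f, *boxes[g.id]) > best_d:
                break
            d = filament_pair_distance(f, g)
            if d < best_d or (d == best_d and g.id < best_id):
                best_d, best_id = d, g.id
        rows.append((f.id, best_id, best_d))
    return pd.DataFrame(rows, columns=["filament_id", "nearest_id", "distance_nm"])


@dataclass(frozen=True)
class NetworkStats:
    """Summary statistics of a filament network and its interactions.

    Standard deviations are population SDs (divisor N).  Interaction fields
    are ``None`` when no interactions were supplied (absent, not zero).
    ``distance_bin_fractions`` maps each distance upper bound (nm) to the
    fraction of interactions with that minimum distance; the final key
    ``inf`` collects everything beyond the last edge.
    """

    n_filaments: int
    density_per_um3: float
    mean_length_nm: float
    sd_length_nm: float
    mean_nn_distance_nm: float | None
    sd_nn_distance_nm: float | None
    n_interactions: int
    mean_interaction_length_nm: float | None
    sd_interaction_length_nm: float | None
    distance_bin_fractions: dict[float, float] | None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        if self.distance_bin_fractions is not None:
            d["distance_bin_fractions"] = {
                ("inf" if np.isinf(k) else str(k)): v
                for k, v in self.distance_bin_fractions.items()
            }
        return d


def network_stats(network: FilamentNetwork,
                  interactions: Sequence[Interaction] | None = None,
                  bins: Iterable[float] = DEFAULT_DISTANCE_BINS) -> NetworkStats:
    """Density, length, nearest-neighbor and interaction statistics.

    The caller is expected to have applied :func:`~midzone.filaments.filter_short`
    (100 nm) beforehand, matching the tracing detection limit.
    """
    lengths = network.lengths()
    n = len(network)
    density = n / network.volume.volume_um3 if network.volume is not None else np.nan

    mean_nn = sd_nn = None
    if n >= 2:
        nn = nearest_neighbor_distances(network)["distance_nm"].to_numpy()
        mean_nn, sd_nn = float(nn.mean()), float(nn.std(ddof=0))

    its = list(interactions) if interactions is not None else []
    if its:
        il = np.array([i.length for i in its])
        mean_il, sd_il = float(il.mean()), float(il.std(ddof=0))
        md = np.array([i.min_distance for i in its])
        edges = sorted(float(e) for e in bins)
        fractions: dict[float, float] = {}
        prev = -np.inf
        for e in edges:
            fractions[e] = float(((md > prev) & (md <= e)).mean())
            prev = e
        fractions[np.inf] = float((md > prev).mean())
    else:
        mean_il = sd_il = None
        fractions = None

    return NetworkStats(
        n_filaments=n,
        density_per_um3=float(density),
        mean_length_nm=float(lengths.mean()) if n else np.nan,
        sd_length_nm=float(lengths.std(ddof=0)) if n else np.nan,
        mean_nn_distance_nm=mean_nn,
        sd_nn_distance_nm=sd_nn,
        n_interactions=len(its),
        mean_interaction_length_nm=mean_il,
        sd_interaction_length_nm=sd_il,
        distance_bin_fractions=fractions,
    )


def interactions_to_csv(interactions: Sequence[Interaction], path: str | Path) -> None:
    """Export the interaction spreadsheet."""
    rows = ["source_id,target_id,start_nm,end_nm,length_nm,min_distance_nm,angle_deg"]
    for i in interactions:
        rows.append(f"{i.source_id},{i.target_id},{i.start_arc:.3f},{i.end_arc:.3f},"
                    f"{i.length:.3f},{i.min_distance:.3f},{i.angle:.3f}")
    Path(path).write_text("\n".join(rows) + "\n")
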