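"""Data model and I/O for traced 3D microtubule networks.

Filaments are open polylines in nanometre coordinates, as produced by
electron-tomography tracing.  A :class:`FilamentNetwork` bundles the
filaments of one reconstructed spindle volume together with the bounding
volume used as the denominator of density statistics.

Supported on-disk formats:

* Amira SpatialGraph ASCII (``.am``) — the tracing tool's native export.
  Only the geometric sections (vertices, edge connectivity, per-edge point
  counts, edge point coordinates) are consumed; thickness/radius attributes
  are ignored.
* CSV polylines with header ``filament_id,x,y,z`` (nm), ordered by filament
  then point index.
* A JSON export used for fixtures.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import InvariantError, SpatialGraphParseError, UnsupportedDialectError

NM_PER_UM = 1000.0
#: nm^3 -> um^3
_UM3_PER_NM3 = 1e-9

__all__ = [
    "Filament",
    "BoundingBox",
    "FilamentNetwork",
    "read_spatialgraph",
    "write_spatialgraph",
    "read_csv_network",
    "write_csv_network",
    "network_to_json",
    "network_from_json",
    "filter_short",
]


@dataclass(frozen=True)
class Filament:
    """One traced microtubule: an ordered 3D polyline in nm.

    Parameters
    ----------
    id
        Unique integer id within a network.
    points
        ``(n, 3)`` array of coordinates in nm, ``n >= 2``, consecutive
        points distinct.
    plus_end
        Which terminus is the plus end: ``"start"``, ``"end"`` or ``None``
        when the polarity of the trace is unknown.
    """

    id: int
    points: np.ndarray
    plus_end: str | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InvariantError(f"filament {self.id}: points must be (n, 3)")
        if pts.shape[0] < 2:
            raise InvariantError(f"filament {self.id}: needs >= 2 points")
        if not np.all(np.isfinite(pts)):
            raise InvariantError(f"filament {self.id}: non-finite coordinate")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise InvariantError(f"filament {self.id}: consecutive duplicate points")
        if self.plus_end not in (None, "start", "end"):
            raise InvariantError(f"filament {self.id}: plus_end must be 'start'/'end'/None")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def length(self) -> float:
        """Arc length in nm."""
        return float(self.segment_lengths.sum())

    @property
    def orientation(self) -> np.ndarray:
        """Unit direction vector start -> end."""
        v = self.points[-1] - self.points[0]
        n = np.linalg.norm(v)
        if n == 0.0:
            raise InvariantError(f"filament {self.id}: closed loop has no orientation")
        return v / n

    @property
    def plus_direction(self) -> np.ndarray:
        """Unit vector pointing toward the plus end (requires ``plus_end``)."""
        if self.plus_end is None:
            raise InvariantError(f"filament {self.id}: plus end unknown")
        d = self.orientation
        return d if self.plus_end == "end" else -d


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in nm."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=float)
        hi = np.asarray(self.hi, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise InvariantError("bounding box corners must be length-3")
        if np.any(hi <= lo):
            raise InvariantError("bounding box must have positive extent on every axis")
        lo.setflags(write=False)
        hi.setflags(write=False)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def extent(self) -> np.ndarray:
        return self.hi - self.lo

    @property
    def volume_nm3(self) -> float:
        return float(np.prod(self.extent))

    @property
    def volume_um3(self) -> float:
        return self.volume_nm3 * _UM3_PER_NM3

    def contains(self, points: np.ndarray, tol: float = 1.0) -> bool:
        pts = np.asarray(points, dtype=float)
        return bool(np.all(pts >= self.lo - tol) and np.all(pts <= self.hi + tol))


def _tight_box(filaments: Sequence[Filament]) -> BoundingBox:
    pts = np.vstack([f.points for f in filaments])
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    # degenerate axes (e.g. a planar network) get a 1 nm pad so volume > 0
    pad = np.where(hi - lo <= 0, 0.5, 0.0)
    return BoundingBox(lo - pad, hi + pad)


@dataclass(frozen=True)
class FilamentNetwork:
    """A set of filaments plus the bounding volume of the reconstruction.

    ``volume`` defaults to the tight axis-aligned box of all points when the
    source file declares none; density statistics divide by its volume in
    um^3.  ``chromosome_distance`` (um) records the anaphase stage of the
    spindle the network was traced from, when known.
    """

    filaments: tuple[Filament, ...]
    volume: BoundingBox | None = None
    label: str = ""
    chromosome_distance: float | None = None

    def __post_init__(self) -> None:
        fils = tuple(self.filaments)
        ids = [f.id for f in fils]
        if len(set(ids)) != len(ids):
            raise InvariantError("filament ids must be unique")
        vol = self.volume
        if vol is None and fils:
            vol = _tight_box(fils)
        if vol is not None:
            for f in fils:
                if not vol.contains(f.points, tol=1.0):
                    raise InvariantError(f"filament {f.id} outside bounding volume")
        object.__setattr__(self, "filaments", fils)
        object.__setattr__(self, "volume", vol)

    def __len__(self) -> int:
        return len(self.filaments)

    def __iter__(self) -> Iterator[Filament]:
        return iter(self.filaments)

    def get(self, fid: int) -> Filament:
        for f in self.filaments:
            if f.id == fid:
                return f
        raise KeyError(fid)

    def lengths(self) -> np.ndarray:
        return np.array([f.length for f in self.filaments])


def filter_short(network: FilamentNetwork, min_length: float) -> FilamentNetwork:
    """Drop filaments with arc length below ``min_length`` nm.

    Traces shorter than the tracing detection limit (100 nm for the
    tomographic data this models) are excluded from all statistics; ids of
    the surviving filaments are preserved.
    """
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    kept = tuple(f for f in network.filaments if f.length >= min_length)
    return replace(network, filaments=kept)


# ---------------------------------------------------------------------------
# Amira SpatialGraph ASCII
# ---------------------------------------------------------------------------

_DEFINE_RE = re.compile(r"^define\s+(VERTEX|EDGE|POINT)\s+(\d+)",
                        re.IGNORECASE | re.MULTILINE)
_SECTION_RE = re.compile(
    r"(VERTEX|EDGE|POINT)\s*\{\s*(?:float|int)\s*(?:\[\s*(\d+)\s*\])?\s*(\w+)\s*\}\s*@(\d+)"
)


def read_spatialgraph(path: str | Path, unit_nm: float = 1.0,
                      label: str = "") -> FilamentNetwork:
    """Read an ASCII Amira SpatialGraph file.

    One filament is created per edge, its points taken in file order from
    the ``EdgePointCoordinates`` section.  File coordinates are multiplied
    by ``unit_nm`` (default: file is already in nm).
    """
    text = Path(path).read_text(errors="replace")
    header = text[:512]
    if "BINARY" in header.upper():
        raise UnsupportedDialectError(f"{path}: binary SpatialGraph is not supported")
    if "AmiraMesh" not in header and "HyperSurface" not in header:
        raise SpatialGraphParseError(f"{path}: not an AmiraMesh file")

    counts: dict[str, int] = {}
    for m in _DEFINE_RE.finditer(text):
        counts[m.group(1).upper()] = int(m.group(2))
    for need in ("VERTEX", "EDGE", "POINT"):
        if need not in counts:
            raise SpatialGraphParseError(f"{path}: missing 'define {need}' declaration")

    sections: dict[str, str] = {}  # attribute name -> data marker
    for m in _SECTION_RE.finditer(text):
        sections[m.group(3)] = m.group(4)
    for need in ("EdgeConnectivity", "NumEdgePoints", "EdgePointCoordinates"):
        if need not in sections:
            raise SpatialGraphParseError(f"{path}: missing section '{need}'")

    blocks: dict[str, list[str]] = {}
    marker = None
    for line in text.splitlines():
        s = line.strip()
        if re.fullmatch(r"@\d+", s):
            marker = s[1:]
            blocks[marker] = []
        elif marker is not None and s:
            blocks[marker].append(s)

    def _numbers(attr: str, dtype) -> np.ndarray:
        mk = sections[attr]
        if mk not in blocks:
            raise SpatialGraphParseError(f"{path}: data block @{mk} for '{attr}' missing")
        try:
            return np.array(" ".join(blocks[mk]).split(), dtype=dtype)
        except ValueError as exc:
            raise SpatialGraphParseError(f"{path}: bad value in '{attr}': {exc}") from exc

    n_edges = counts["EDGE"]
    npts_per_edge = _numbers("NumEdgePoints", int)
    if npts_per_edge.size != n_edges:
        raise SpatialGraphParseError(
            f"{path}: EDGE count {n_edges} != NumEdgePoints entries {npts_per_edge.size}"
        )
    coords = _numbers("EdgePointCoordinates", float)
    if coords.size != 3 * counts["POINT"]:
        raise SpatialGraphParseError(
            f"{path}: POINT count {counts['POINT']} != coordinate rows {coords.size // 3}"
        )
    if int(npts_per_edge.sum()) != counts["POINT"]:
        raise SpatialGraphParseError(
            f"{path}: NumEdgePoints sum {int(npts_per_edge.sum())} != POINT count"
        )
    coords = coords.reshape(-1, 3) * unit_nm

    filaments = []
    offset = 0
    for i, n in enumerate(npts_per_edge):
        filaments.append(Filament(id=i, points=coords[offset:offset + n]))
        offset += int(n)
    return FilamentNetwork(filaments=tuple(filaments), label=label or Path(path).stem)


def write_spatialgraph(network: FilamentNetwork, path: str | Path) -> None:
    """Write the ASCII SpatialGraph dialect read by :func:`read_spatialgraph`."""
    fils = network.filaments
    n_points = sum(f.n_points for f in fils)
    lines = [
        "# AmiraMesh 3D ASCII 2.0",
        "",
        f"define VERTEX {2 * len(fils)}",
        f"define EDGE {len(fils)}",
        f"define POINT {n_points}",
        "",
        'Parameters { ContentType "HxSpatialGraph" }',
        "",
        "VERTEX { float[3] VertexCoordinates } @1",
        "EDGE { int[2] EdgeConnectivity } @2",
        "EDGE { int NumEdgePoints } @3",
        "POINT { float[3] EdgePointCoordinates } @4",
        "",
        "@1",
    ]
    for f in fils:
        for p in (f.points[0], f.points[-1]):
            lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    lines.append("")
    lines.append("@2")
    for i in range(len(fils)):
        lines.append(f"{2 * i} {2 * i + 1}")
    lines.append("")
    lines.append("@3")
    for f in fils:
        lines.append(str(f.n_points))
    lines.append("")
    lines.append("@4")
    for f in fils:
        for p in f.points:
            lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}")
    lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# CSV polylines
# ---------------------------------------------------------------------------

def read_csv_network(path: str | Path, label: str = "") -> FilamentNetwork:
    """Read ``filament_id,x,y,z`` CSV polylines (coordinates in nm)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise SpatialGraphParseError(f"{path}: {exc}") from exc
    required = ["filament_id", "x", "y", "z"]
    if list(df.columns[:4]) != required:
        raise SpatialGraphParseError(
            f"{path}: header must start with {','.join(required)}"
        )
    for col in required:
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based + header line
            raise SpatialGraphParseError(f"{path}: non-numeric '{col}' at row {row}")
    filaments = []
    for fid, grp in df.groupby("filament_id", sort=True):
        pts = grp[["x", "y", "z"]].to_numpy(dtype=float)
        filaments.append(Filament(id=int(fid), points=pts))
    return FilamentNetwork(filaments=tuple(filaments), label=label or Path(path).stem)


def write_csv_network(network: FilamentNetwork, path: str | Path) -> None:
    """Write CSV polylines; coordinates printed to 1e-6 nm."""
    rows = ["filament_id,x,y,z"]
    for f in network.filaments:
        for p in f.points:
            rows.append(f"{f.id},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}")
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# JSON fixtures
# ---------------------------------------------------------------------------

def network_to_json(network: FilamentNetwork) -> str:
    obj = {
        "label": network.label,
        "chromosome_distance": network.chromosome_distance,
        "volume": None if network.volume is None else
            {"lo": network.volume.lo.tolist(), "hi": network.volume.hi.tolist()},
        "filaments": [
            {"id": f.id, "plus_end": f.plus_end, "points": f.points.tolist()}
            for f in network.filaments
        ],
    }
    return json.dumps(obj, indent=1)


def network_from_json(text: str) -> FilamentNetwork:
    obj = json.loads(text)
    vol = obj.get("volume")
    return FilamentNetwork(
        filaments=tuple(
            Filament(id=f["id"], points=np.array(f["points"]), plus_end=f.get("plus_end"))
            for f in obj["filaments"]
        ),
        volume=None if vol is None else BoundingBox(np.array(vol["lo"]), np.array(vol["hi"])),
        label=obj.get("label", ""),
        chromosome_distance=obj.get("chromosome_distance"),
    )
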