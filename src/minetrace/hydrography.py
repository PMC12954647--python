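"""River-network data model: segments, connectivity, flow grid, intervals.

The hydrography is a HydroRIVERS-style vector network: each reach
(:class:`RiverSegment`) is a polyline with a single downstream pointer, a
geodesic length, a limnicity percentage (percent lake area along the
reach) and a main-basin identifier.  Downstream pointers must form a
forest oriented toward terminal sinks; braided reaches (more than one
downstream neighbour) are not representable and are rejected at load.

Offsets along a segment are measured in km from the UPSTREAM endpoint;
sub-reach intervals are half-open ``[start, end)`` for merging purposes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

import numpy as np
from shapely.geometry import LineString, Point
from shapely.ops import substring

from .geodesy import polyline_length_km, point_distance_km

#: ESRI/ArcGIS D8 direction codes -> (row step, col step), row 0 at the top.
D8_ESRI: dict[int, tuple[int, int]] = {
    1: (0, 1),     # E
    2: (1, 1),     # SE
    4: (1, 0),     # S
    8: (1, -1),    # SW
    16: (0, -1),   # W
    32: (-1, -1),  # NW
    64: (-1, 0),   # N
    128: (-1, 1),  # NE
}


class NetworkError(ValueError):
    """Structurally invalid river network."""


class LinkageError(ValueError):
    """A point expected to lie on a segment is too far from it."""


@dataclass
class RiverSegment:
    """One reach of the hydrography.

    ``length_km`` is derived from the geometry (in the network's mode)
    when not supplied.  ``discharge_m3s`` is carried through untouched
    and never enters any computation.
    """

    segment_id: str
    geometry: LineString
    downstream_id: Optional[str] = None
    limnicity_pct: float = 0.0
    basin_id: str = ""
    length_km: Optional[float] = None
    discharge_m3s: Optional[float] = None

    @property
    def is_lentic(self) -> bool:
        return self.limnicity_pct > 20.0


class RiverNetwork:
    """Segments keyed by id plus the inverse (upstream) index."""

    def __init__(self, segments: Iterable[RiverSegment], mode: str = "planar"):
        self.mode = mode
        self.segments: dict[str, RiverSegment] = {}
        for seg in segments:
            if seg.segment_id in self.segments:
                raise NetworkError(f"duplicate segment id {seg.segment_id!r}")
            if seg.length_km is None:
                seg.length_km = polyline_length_km(seg.geometry.coords, mode)
            self.segments[seg.segment_id] = seg
        self.upstream: dict[str, set[str]] = {sid: set() for sid in self.segments}
        for seg in self.segments.values():
            if seg.downstream_id is not None and seg.downstream_id in self.upstream:
                self.upstream[seg.downstream_id].add(seg.segment_id)

    def __len__(self) -> int:
        return len(self.segments)

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self.segments

    def __getitem__(self, segment_id: str) -> RiverSegment:
        try:
            return self.segments[segment_id]
        except KeyError:
            raise NetworkError(f"unknown segment id {segment_id!r}") from None

    def downstream_of(self, segment_id: str) -> Optional[RiverSegment]:
        did = self[segment_id].downstream_id
        return self.segments.get(did) if did is not None else None

    def walk_downstream(self, segment_id: str) -> Iterator[RiverSegment]:
        """Yield the segment and every segment below it, sink-ward."""
        seen: set[str] = set()
        seg: Optional[RiverSegment] = self[segment_id]
        while seg is not None and seg.segment_id not in seen:
            seen.add(seg.segment_id)
            yield seg
            seg = self.downstream_of(seg.segment_id)

    def on_same_path(self, a: str, b: str) -> bool:
        """True if one segment is downstream of (or equal to) the other."""
        if a == b:
            return True
        if any(s.segment_id == b for s in self.walk_downstream(a)):
            return True
        return any(s.segment_id == a for s in self.walk_downstream(b))

    def total_length_km(self) -> float:
        return sum(s.length_km for s in self.segments.values())

    def basin_lengths_km(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for s in self.segments.values():
            out[s.basin_id] = out.get(s.basin_id, 0.0) + s.length_km
        return out


@dataclass(frozen=True, order=True)
class SegmentInterval:
    """Half-open sub-reach ``[start_km, end_km)`` of one segment."""

    segment_id: str
    start_km: float
    end_km: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_km < self.end_km):
            raise ValueError(
                f"invalid interval [{self.start_km}, {self.end_km}) "
                f"on {self.segment_id}")

    @property
    def length_km(self) -> float:
        return self.end_km - self.start_km


@dataclass
class ValidationReport:
    """Invariant violations found in a network; empty report == valid."""

    cycles: list[list[str]] = field(default_factory=list)
    dangling: list[tuple[str, str]] = field(default_factory=list)
    bad_length: list[str] = field(default_factory=list)
    bad_limnicity: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.cycles or self.dangling
                    or self.bad_length or self.bad_limnicity)

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        if self.ok:
            return "network valid"
        parts = []
        if self.cycles:
            parts.append(f"{len(self.cycles)} cycle(s): {self.cycles[:3]}")
        if self.dangling:
            parts.append(f"dangling downstream ids: {self.dangling[:5]}")
        if self.bad_length:
            parts.append(f"non-positive lengths: {self.bad_length[:5]}")
        if self.bad_limnicity:
            parts.append(f"limnicity out of [0,100]: {self.bad_limnicity[:5]}")
        return "; ".join(parts)


def validate_network(network: RiverNetwork) -> ValidationReport:
    """Check the forest/attribute invariants and report every violation."""
    report = ValidationReport()
    for seg in network.segments.values():
        if seg.downstream_id is not None and seg.downstream_id not in network.segments:
            report.dangling.append((seg.segment_id, seg.downstream_id))
        if seg.length_km is None or seg.length_km <= 0:
            report.bad_length.append(seg.segment_id)
        if not (0.0 <= seg.limnicity_pct <= 100.0):
            report.bad_limnicity.append(seg.segment_id)

    # cycle detection on downstream pointers (0 = new, 1 = on path, 2 = done)
    state: dict[str, int] = {sid: 0 for sid in network.segments}
    for start in network.segments:
        if state[start]:
            continue
        path: list[str] = []
        cur: Optional[str] = start
        while cur is not None and cur in state and state[cur] == 0:
            state[cur] = 1
            path.append(cur)
            cur = network.segments[cur].downstream_id
        if cur is not None and cur in state and state[cur] == 1:
            report.cycles.append(path[path.index(cur):])
        for sid in path:
            state[sid] = 2
    return report


def geodesic_length(geometry: LineString, mode: str = "geodesic") -> float:
    """Length of a polyline in km (ellipsoidal or planar per mode)."""
    return polyline_length_km(geometry.coords, mode)


def locate_offset(segment: RiverSegment, point: Point, mode: str = "planar",
                  tol_km: float = 1.0) -> float:
    """Distance along the segment, km from the upstream endpoint.

    The point is projected onto the polyline; a point farther than
    ``tol_km`` from it indicates a linkage bug and raises
    :class:`LinkageError`.
    """
    line = segment.geometry
    gap = line.distance(point)
    if mode == "geodesic":
        gap *= 111.0  # degrees -> rough km, tolerance check only
    if gap > tol_km:
        raise LinkageError(
            f"point {point.wkt} is {gap:.3f} km from segment "
            f"{segment.segment_id}")
    frac = line.project(point, normalized=True)
    return min(max(frac, 0.0), 1.0) * segment.length_km


def interval_geometry(network: RiverNetwork,
                      interval: SegmentInterval) -> LineString:
    """Polyline of a sub-reach interval (arc-length fractional substring)."""
    seg = network[interval.segment_id]
    a = interval.start_km / seg.length_km
    b = interval.end_km / seg.length_km
    return substring(seg.geometry, min(a, 1.0), min(b, 1.0), normalized=True)


def orient_segments(segments: Iterable[RiverSegment]) -> list[RiverSegment]:
    """Ensure vertices run upstream -> downstream.

    Vector hydrography does not guarantee vertex order; a segment is
    flipped when its first vertex is nearer its downstream neighbour's
    polyline than its last vertex is.
    """
    segs = list(segments)
    by_id = {s.segment_id: s for s in segs}
    for seg in segs:
        down = by_id.get(seg.downstream_id) if seg.downstream_id else None
        if down is None:
            continue
        first, last = Point(seg.geometry.coords[0]), Point(seg.geometry.coords[-1])
        if first.distance(down.geometry) < last.distance(down.geometry) - 1e-12:
            seg.geometry = LineString(list(seg.geometry.coords)[::-1])
    return segs


@dataclass
class FlowGrid:
    """D8 flow-direction raster plus an aligned stream mask.

    ``direction`` holds D8 codes (``codes`` maps code -> (drow, dcol);
    ``sink_code`` terminates a walk).  ``stream_index`` holds, per cell,
    an index into ``segment_ids`` or -1 for non-stream cells.  The
    georeference is a north-up affine: ``x_origin``/``y_origin`` are the
    WEST and NORTH edges, cells are square with side ``cell_size`` (km in
    planar mode, degrees in geodesic mode).
    """

    direction: np.ndarray
    stream_index: np.ndarray
    segment_ids: list[str]
    x_origin: float
    y_origin: float
    cell_size: float
    codes: Mapping[int, tuple[int, int]] = field(
        default_factory=lambda: dict(D8_ESRI))
    sink_code: int = 0

    def __post_init__(self) -> None:
        if self.direction.shape != self.stream_index.shape:
            raise ValueError("direction and stream mask shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.direction.shape

    def cell_of(self, x: float, y: float) -> Optional[tuple[int, int]]:
        """Row/col of the cell containing (x, y), or None outside extent."""
        col = int(np.floor((x - self.x_origin) / self.cell_size))
        row = int(np.floor((self.y_origin - y) / self.cell_size))
        nrow, ncol = self.shape
        if 0 <= row < nrow and 0 <= col < ncol:
            return row, col
        return None

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_origin + (col + 0.5) * self.cell_size
        y = self.y_origin - (row + 0.5) * self.cell_size
        return x, y

    def segment_at(self, row: int, col: int) -> Optional[str]:
        idx = int(self.stream_index[row, col])
        return self.segment_ids[idx] if idx >= 0 else None


def validate_grid(grid: FlowGrid, network: RiverNetwork) -> list[str]:
    """Ids present in the stream mask but missing from the network."""
    present = {grid.segment_ids[i]
               for i in np.unique(grid.stream_index) if i >= 0}
    return sorted(sid for sid in present if sid not in network.segments)
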