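"""Downstream propagation of potential contamination.

From each entry point, consecutive downstream reaches are accumulated
until the attenuation distance is exhausted; the final reach is cropped
so the traced total equals the distance exactly.  Tracing stops before
any segment with limnicity above the threshold (lentic systems act as
contaminant sinks) and at terminal sinks.  River portions inside a mine
footprint are directly exposed and included verbatim; propagation from
an exit point restarts with the full attenuation budget.

Overlapping reaches from different mines or methods are merged by
:func:`dissolve` so every affected river stretch is represented once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .attenuation import Scenario
from .hydrography import RiverNetwork, SegmentInterval
from .linkage import DirectExposure, EntryPoint
from .mines import MinePolygon

#: adjacency tolerance for interval merging, km
MERGE_TOL_PLANAR = 1e-9
MERGE_TOL_GEODESIC = 1e-6

LIMNICITY_THRESHOLD_PCT = 20.0


@dataclass(frozen=True)
class ExposedReach:
    """A sub-reach attributed to one or more source mines.

    ``direct`` marks in-mine (intersection-based) intervals, which are
    exempt from the lentic-termination rule.
    """

    interval: SegmentInterval
    sources: frozenset[str]
    commodities: frozenset[str] = frozenset()
    statuses: frozenset[str] = frozenset()
    direct: bool = False

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("an exposed reach needs at least one source mine")


@dataclass
class ExposureSet:
    """Exposed reaches under one attenuation scenario."""

    reaches: list[ExposedReach] = field(default_factory=list)
    scenario: Scenario = Scenario.MODERATE
    dissolved: bool = False

    def __iter__(self):
        return iter(self.reaches)

    def __len__(self) -> int:
        return len(self.reaches)


def trace_downstream(network: RiverNetwork, start_segment: str,
                     start_offset_km: float, distance_km: float,
                     limnicity_threshold: float = LIMNICITY_THRESHOLD_PCT,
                     tol: float = 1e-12) -> list[SegmentInterval]:
    """Intervals covered by a downstream trace of ``distance_km``.

    The first interval starts at ``start_offset_km`` on the start
    segment; each following segment is consumed whole until the budget
    runs out, and the final interval is cropped so the traced total
    equals the distance.  A start segment above the limnicity threshold
    yields nothing; tracing stops before any downstream segment above
    it, and at sinks, possibly leaving the total short of the distance.
    """
    seg = network[start_segment]
    if not (-tol <= start_offset_km <= seg.length_km + tol):
        raise ValueError(
            f"start offset {start_offset_km} outside [0, {seg.length_km}] "
            f"on {start_segment}")
    if distance_km < 0:
        raise ValueError("distance_km must be >= 0")
    out: list[SegmentInterval] = []
    if seg.limnicity_pct > limnicity_threshold:
        return out
    remaining = distance_km
    offset = min(max(start_offset_km, 0.0), seg.length_km)
    while remaining > tol:
        end = min(seg.length_km, offset + remaining)
        if end > offset + tol:
            out.append(SegmentInterval(seg.segment_id, offset, end))
            remaining -= end - offset
        if end < seg.length_km - tol or remaining <= tol:
            break
        nxt = network.downstream_of(seg.segment_id)
        if nxt is None or nxt.limnicity_pct > limnicity_threshold:
            break
        seg, offset = nxt, 0.0
    return out


def trace_mine(network: RiverNetwork, mine: MinePolygon,
               entry: Optional[EntryPoint], direct: Optional[DirectExposure],
               distance_km: float,
               limnicity_threshold: float = LIMNICITY_THRESHOLD_PCT
               ) -> list[ExposedReach]:
    """All exposed reaches attributable to one mine.

    Union of (a) the downstream trace from the centroid-based entry,
    (b) every in-mine interval verbatim, and (c) a full-distance trace
    from each exit point.  Overlaps are retained; dissolve is a later
    stage.
    """
    if entry is None and (direct is None or not direct.intervals):
        return []
    tags = dict(sources=frozenset({mine.mine_id}),
                commodities=mine.commodities,
                statuses=frozenset({mine.status}))
    reaches: list[ExposedReach] = []
    if entry is not None:
        for iv in trace_downstream(network, entry.segment_id, entry.offset_km,
                                   distance_km, limnicity_threshold):
            reaches.append(ExposedReach(interval=iv, **tags))
    if direct is not None:
        for iv in direct.intervals:
            reaches.append(ExposedReach(interval=iv, direct=True, **tags))
        for exit_point in direct.exit_points:
            for iv in trace_downstream(network, exit_point.segment_id,
                                       exit_point.offset_km, distance_km,
                                       limnicity_threshold):
                reaches.append(ExposedReach(interval=iv, **tags))
    return reaches


def _merge_group(reaches: list[ExposedReach], tol: float) -> list[ExposedReach]:
    """Merge overlapping/adjacent reaches on a single segment."""
    ordered = sorted(reaches, key=lambda r: (r.interval.start_km,
                                             r.interval.end_km))
    merged: list[ExposedReach] = []
    cur = ordered[0]
    for nxt in ordered[1:]:
        if nxt.interval.start_km <= cur.interval.end_km + tol:
            cur = ExposedReach(
                interval=SegmentInterval(
                    cur.interval.segment_id, cur.interval.start_km,
                    max(cur.interval.end_km, nxt.interval.end_km)),
                sources=cur.sources | nxt.sources,
                commodities=cur.commodities | nxt.commodities,
                statuses=cur.statuses | nxt.statuses,
                direct=cur.direct or nxt.direct)
        else:
            merged.append(cur)
            cur = nxt
    merged.append(cur)
    return merged


def dissolve(exposure: ExposureSet, tol: float = MERGE_TOL_PLANAR
             ) -> ExposureSet:
    """Merge overlapping/adjacent reaches into maximal disjoint intervals.

    Per segment, intervals closer than ``tol`` are unioned and their
    source/commodity/status sets merged.  Idempotent; total length never
    exceeds the sum of input lengths.
    """
    by_segment: dict[str, list[ExposedReach]] = {}
    for reach in exposure.reaches:
        by_segment.setdefault(reach.interval.segment_id, []).append(reach)
    out: list[ExposedReach] = []
    for sid in sorted(by_segment):
        out.extend(_merge_group(by_segment[sid], tol))
    return ExposureSet(reaches=out, scenario=exposure.scenario, dissolved=True)


def _union_length(intervals: Iterable[tuple[float, float]],
                  tol: float = MERGE_TOL_PLANAR) -> float:
    spans = sorted(intervals)
    total = 0.0
    cur_a: Optional[float] = None
    cur_b = 0.0
    for a, b in spans:
        if cur_a is None or a > cur_b + tol:
            if cur_a is not None:
                total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    if cur_a is not None:
        total += cur_b - cur_a
    return total


def total_length(exposure: ExposureSet | Iterable[ExposedReach],
                 weights: Optional[Mapping[str, float]] = None,
                 tol: float = MERGE_TOL_PLANAR) -> float:
    """Total exposed length in km, optionally demand-share weighted.

    Unweighted mode sums interval lengths (call after :func:`dissolve`
    for a de-duplicated total).  Weighted mode expects per-mine reaches
    (before the cross-mine dissolve): per segment, each mine's own
    intervals are unioned, scaled by that mine's weight, summed over
    mines, and capped at the unweighted union length of the segment.
    Reaches whose sources were already merged across mines cannot be
    weighted and raise ``ValueError``.
    """
    reaches = list(exposure.reaches if isinstance(exposure, ExposureSet)
                   else exposure)
    if weights is None:
        return sum(r.interval.length_km for r in reaches)

    per_segment: dict[str, dict[str, list[tuple[float, float]]]] = {}
    for r in reaches:
        if len(r.sources) != 1:
            raise ValueError(
                "weighted totals need per-mine reaches (single source); "
                "run before the cross-mine dissolve")
        (mine_id,) = r.sources
        per_segment.setdefault(r.interval.segment_id, {}) \
            .setdefault(mine_id, []).append(
                (r.interval.start_km, r.interval.end_km))
    total = 0.0
    for mines_on_segment in per_segment.values():
        weighted = sum(weights.get(mid, 0.0) * _union_length(spans, tol)
                       for mid, spans in mines_on_segment.items())
        cap = _union_length(
            (span for spans in mines_on_segment.values() for span in spans),
            tol)
        total += min(weighted, cap)
    return total


def contains(outer: ExposureSet, inner: ExposureSet, tol: float = 1e-9) -> bool:
    """True if every inner interval is covered by the outer set's union."""
    cover: dict[str, list[tuple[float, float]]] = {}
    for r in dissolve(outer, tol).reaches:
        cover.setdefault(r.interval.segment_id, []).append(
            (r.interval.start_km, r.interval.end_km))
    for r in inner.reaches:
        spans = cover.get(r.interval.segment_id, [])
        if not any(a - tol <= r.interval.start_km
                   and r.interval.end_km <= b + tol for a, b in spans):
            return False
    return True
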