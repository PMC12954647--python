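"""Hand-built fixture worlds with analytically known results.

The planted world is a 12-segment planar network in two basins with
three mines: one linked mid-segment through the flow grid, one
straddling a river, and one beyond the 10 km buffer.  Every expected
length below is hand arithmetic on the axis-aligned geometry.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import LineString, Point, box

from minetrace.attenuation import AttenuationTable
from minetrace.conservation import ConservationSite
from minetrace.hydrography import D8_ESRI, FlowGrid, RiverNetwork, RiverSegment
from minetrace.mines import MineCluster, MinePolygon
from minetrace.synthetic import SyntheticWorld, WorldConfig

_CODE_OF = {delta: code for code, delta in D8_ESRI.items()}

# neighbour preference for downslope derivation: N, NE, E, SE, S, SW, W, NW
_NEIGHBOUR_ORDER = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1),
                    (0, -1), (-1, -1)]


def derive_d8_toward_streams(stream_index: np.ndarray) -> np.ndarray:
    """D8 codes draining every non-stream cell to its nearest stream cell.

    Each cell points at the first neighbour (N-first preference order)
    whose centre is strictly closer to the nearest stream-cell centre,
    guaranteeing every walk terminates on a stream.  Stream cells are
    left as sinks; callers overwrite them with along-stream directions.
    """
    nrow, ncol = stream_index.shape
    stream_rc = np.argwhere(stream_index >= 0)
    rr, cc = np.meshgrid(np.arange(nrow), np.arange(ncol), indexing="ij")
    dist = np.full((nrow, ncol), np.inf)
    for sr, sc in stream_rc:
        d = np.hypot(rr - sr, cc - sc)
        dist = np.minimum(dist, d)
    direction = np.zeros((nrow, ncol), dtype=np.int32)
    for r in range(nrow):
        for c in range(ncol):
            if stream_index[r, c] >= 0:
                continue
            best, best_delta = dist[r, c], None
            for dr, dc in _NEIGHBOUR_ORDER:
                nr, nc = r + dr, c + dc
                if 0 <= nr < nrow and 0 <= nc < ncol and dist[nr, nc] < best:
                    best, best_delta = dist[nr, nc], (dr, dc)
            if best_delta is not None:
                direction[r, c] = _CODE_OF[best_delta]
    return direction


def _cells(x0: int, y0: int, x1: int, y1: int) -> list[tuple[int, int]]:
    """Inclusive integer cell range, single row or column."""
    if y0 == y1:
        step = 1 if x1 >= x0 else -1
        return [(x, y0) for x in range(x0, x1 + step, step)]
    step = 1 if y1 >= y0 else -1
    return [(x0, y) for y in range(y0, y1 + step, step)]


#: segment id -> (cell path upstream->downstream, downstream id, limnicity)
PLANTED_SEGMENTS = {
    "S1": (_cells(0, 10, 4, 10), "S3", 0.0),
    "S2": (_cells(5, 14, 5, 11), "S3", 0.0),
    "S3": (_cells(5, 10, 14, 10), "S4", 0.0),
    "S4": (_cells(15, 10, 19, 10), "S5", 0.0),
    "S5": (_cells(20, 10, 29, 10), "S6", 0.0),
    "S6": (_cells(30, 10, 39, 10), "S7", 30.0),   # lentic reservoir reach
    "S7": (_cells(40, 10, 45, 10), None, 0.0),
    "S8": (_cells(20, 15, 20, 11), "S5", 0.0),
    "S9": (_cells(0, 30, 5, 30), "S10", 0.0),
    "S10": (_cells(6, 30, 13, 30), "S11", 0.0),
    "S11": (_cells(14, 30, 19, 30), "S12", 0.0),
    "S12": (_cells(20, 30, 26, 30), None, 0.0),
}

PLANTED_ROWS, PLANTED_COLS = 34, 46


def _center(cx: int, cy: int) -> tuple[float, float]:
    return cx + 0.5, cy + 0.5


def build_planted_network() -> RiverNetwork:
    segments = []
    first_cell_of = {sid: cells[0] for sid, (cells, _, _) in
                     PLANTED_SEGMENTS.items()}
    for sid, (cells, down, limn) in PLANTED_SEGMENTS.items():
        coords = [_center(*rc) for rc in cells]
        if down is not None:
            coords.append(_center(*first_cell_of[down]))
        basin = "B2" if sid in ("S9", "S10", "S11", "S12") else "B1"
        segments.append(RiverSegment(segment_id=sid,
                                     geometry=LineString(coords),
                                     downstream_id=down,
                                     limnicity_pct=limn, basin_id=basin))
    return RiverNetwork(segments, mode="planar")


def build_planted_grid() -> FlowGrid:
    seg_ids = list(PLANTED_SEGMENTS)
    stream_index = np.full((PLANTED_ROWS, PLANTED_COLS), -1, dtype=np.int32)
    for idx, (sid, (cells, _, _)) in enumerate(PLANTED_SEGMENTS.items()):
        for cx, cy in cells:
            stream_index[PLANTED_ROWS - 1 - cy, cx] = idx
    direction = derive_d8_toward_streams(stream_index)
    # along-stream directions for stream cells
    first_cell_of = {sid: cells[0] for sid, (cells, _, _) in
                     PLANTED_SEGMENTS.items()}
    for sid, (cells, down, _) in PLANTED_SEGMENTS.items():
        chain = list(cells) + ([first_cell_of[down]] if down else [])
        for (ax, ay), (bx, by) in zip(chain[:-1], chain[1:]):
            r, c = PLANTED_ROWS - 1 - ay, ax
            direction[r, c] = _CODE_OF[(ay - by, bx - ax)]
        if down is None:
            lx, ly = chain[-1]
            direction[PLANTED_ROWS - 1 - ly, lx] = 0      # terminal sink
    return FlowGrid(direction=direction, stream_index=stream_index,
                    segment_ids=seg_ids, x_origin=0.0,
                    y_origin=float(PLANTED_ROWS), cell_size=1.0)


def build_planted_mines() -> tuple[list[MinePolygon], list[MineCluster]]:
    mines = [
        # routed mid-segment: interior point (2.5, 6.5) drains north to S1
        # at offset 2 km, 4 km away
        MinePolygon(mine_id="M1", cluster_id="CA", geometry=box(2, 6, 3, 7),
                    commodities=frozenset({"gold"})),
        # straddles S3 over x in [8, 11]: direct interval [2.5, 5.5]
        MinePolygon(mine_id="M2", cluster_id="CB", geometry=box(8, 9, 11, 12),
                    commodities=frozenset({"copper"})),
        # nearest stream cell 15 km away -> excluded by the 10 km buffer
        MinePolygon(mine_id="M3", cluster_id="CC",
                    geometry=box(40, 29, 43, 32)),
    ]
    clusters = [
        MineCluster("CA", ["M1"], ["active", "active", "inactive"]),
        MineCluster("CB", ["M2"], ["inactive"]),
        MineCluster("CC", ["M3"], []),
    ]
    return mines, clusters


def build_planted_sites() -> tuple[list[ConservationSite],
                                   list[ConservationSite]]:
    pa = [
        ConservationSite("PA1", "PA", box(12, 8, 22, 13),
                         designation_type="national", iucn_category="II"),
        ConservationSite("PA2", "PA", box(0, 28, 4, 32),
                         designation_type="national", iucn_category="IV",
                         status_flag="proposed"),
        # point site over S12; circle radius 2 -> 4 km chord on the river
        ConservationSite("PA3", "PA", Point(23.5, 30.5),
                         reported_area_km2=4.0 * math.pi,
                         designation_type="international"),
        ConservationSite("PA4", "PA", Point(30.0, 25.0),
                         reported_area_km2=10.0, marine=True),
    ]
    kba = [ConservationSite("KBA1", "KBA", box(18, 8, 26, 12))]
    return pa, kba


def build_planted_world() -> SyntheticWorld:
    mines, clusters = build_planted_mines()
    pa, kba = build_planted_sites()
    return SyntheticWorld(
        config=WorldConfig(seed=0, rows=PLANTED_ROWS, w_cols=PLANTED_COLS,
                           apron_cols=0),
        network=build_planted_network(),
        grid=build_planted_grid(),
        mines=mines, clusters=clusters, pa_sites=pa, kba_sites=kba,
        attenuation=AttenuationTable(),     # no element-specific values
        ground_truth={})


# hand-computed expectations (km) ------------------------------------------

PLANTED_TOTAL_KM = 80.0
PLANTED_BASIN_KM = {"B1": 54.0, "B2": 26.0}

# severe (45.6 km everywhere): dissolved union of M1 and M2
PLANTED_SEVERE = {"S1": [(2.0, 5.0)], "S3": [(0.0, 10.0)],
                  "S4": [(0.0, 5.0)], "S5": [(0.0, 10.0)]}
PLANTED_SEVERE_TOTAL = 28.0
# moderate (6.5 km everywhere)
PLANTED_MODERATE = {"S1": [(2.0, 5.0)], "S3": [(0.0, 10.0)],
                    "S4": [(0.0, 2.0)]}
PLANTED_MODERATE_TOTAL = 15.0

PLANTED_COMMODITY_SEVERE = {"gold": 28.0, "copper": 22.5, "key_etm": 22.5}
PLANTED_STATUS_SEVERE = {"active": 28.0, "inactive": 22.5}
PLANTED_CLEAN_ENERGY_SEVERE = 22.5 * 0.2441          # 5.49225

PLANTED_CPA_NETWORK_KM = 24.0          # combined PA+KBA union
PLANTED_CPA_SEVERE_IN = 14.0
PLANTED_CPA_MODERATE_IN = 5.5
PLANTED_IUCN_NETWORK_KM = 12.5         # PA1 only
PLANTED_IUCN_SEVERE_IN = 10.0

PLANTED_SITE_SEVERE = {  # site -> (exposed_km, total_km)
    "PA1": (10.0, 12.5), "PA2": (0.0, 3.5), "PA3": (0.0, 4.0),
    "KBA1": (8.0, 9.5),
}
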