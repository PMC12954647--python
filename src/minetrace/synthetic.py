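"""Self-consistent synthetic worlds with known ground truth.

A world is a small raster landscape whose drainage is a random spanning
forest over the grid cells: every cell has a D8 parent pointing toward
one of a few edge sinks, streams are the high-flow-accumulation subtree,
and river segments are the confluence-to-confluence paths of stream
cells.  Because the vector network is derived from the same forest as
the D8 field, routing any cell downslope is guaranteed to reach the
stream cell of its own catchment - the property real flow-direction /
hydrography pairs only approximate.

The eastern part of the grid is a stream-free apron draining westward,
which provides mine placements whose nearest watercourse is beyond the
10 km buffer (exercising the exclusion rule).

Generator defaults emulate the study conditions of the global mining
dataset: 48.1% of mines carry commodity labels, 12.7% of mines straddle
a river, activity statuses mix ~14% active / ~26% inactive / ~1%
planned / rest unknown, and mine areas follow a heavy-tailed log-normal
(median ~0.03 km2).  ``brute_force_exposure`` re-implements the
downstream propagation with plain scalar recursion and is used only as
an independent oracle in tests.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import LineString, Point, box
from shapely.strtree import STRtree

from .attenuation import (AttenuationTable, DEFAULT_SCENARIOS, Scenario,
                          resolve_distance)
from .conservation import ConservationSite
from .hydrography import (D8_ESRI, FlowGrid, RiverNetwork, RiverSegment)
from .mines import MineCluster, MinePolygon, canonicalize_commodities
from .tracing import LIMNICITY_THRESHOLD_PCT

_CODE_OF = {delta: code for code, delta in D8_ESRI.items()}


class InfeasibleConfigError(ValueError):
    """The requested world cannot be realized on the configured grid."""


#: synthetic per-commodity attenuation distances (km); calibration values
#: chosen inside the published 6.5-45.6 km bounds, NOT literature values.
SYNTHETIC_ELEMENT_DISTANCES = {
    "gold": 14.0,
    "copper": 30.0,
    "coal": 9.8,
    "silver": 21.0,
    "nickel": 18.0,
}

DEFAULT_COMMODITY_FREQS = {
    "gold": 0.30,
    "coal": 0.22,
    "copper": 0.16,
    "iron": 0.10,
    "silver": 0.06,
    "nickel": 0.05,
    "lithium": 0.04,
    "cobalt": 0.03,
    "graphite": 0.02,
    "rare earth elements": 0.02,
}

DEFAULT_STATUS_FREQS = {
    "active": 0.142,
    "inactive": 0.262,
    "planned": 0.010,
    "unknown": 0.586,
}


@dataclass
class WorldConfig:
    """Parameters of a synthetic world; the seed fixes every draw."""

    seed: int = 0
    rows: int = 48
    w_cols: int = 48          # columns carrying the drainage forest
    apron_cols: int = 16      # stream-free eastern apron
    cell_km: float = 1.0
    n_basins: int = 3
    stream_frac: float = 0.30   # fraction of forest cells that are stream
    lake_frac: float = 0.08     # fraction of segments with limnicity > 20%
    n_mines: int = 24
    straddle_frac: float = 0.127  # fraction of mines overlapping a river
    far_frac: float = 0.08        # mines beyond the 10 km buffer
    area_lognorm_mu: float = -3.5   # ln km2; median ~0.03 km2
    area_lognorm_sigma: float = 2.0
    labeled_frac: float = 0.481
    commodity_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMMODITY_FREQS))
    status_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATUS_FREQS))
    n_pa: int = 6
    n_kba: int = 4
    point_site_frac: float = 0.25
    mode: str = "planar"
    buffer_km: float = 10.0
    limnicity_threshold: float = LIMNICITY_THRESHOLD_PCT
    element_distances_km: dict[str, float] = field(
        default_factory=lambda: dict(SYNTHETIC_ELEMENT_DISTANCES))

    @property
    def cols(self) -> int:
        return self.w_cols + self.apron_cols

    def validate(self) -> None:
        for name in ("stream_frac", "lake_frac", "straddle_frac", "far_frac",
                     "labeled_frac", "point_site_frac"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise InfeasibleConfigError(f"{name} must be in [0, 1]")
        if self.n_basins > self.rows:
            raise InfeasibleConfigError(
                f"{self.n_basins} basins need at least that many rows "
                f"({self.rows} available)")
        if self.rows < 4 or self.w_cols < 4:
            raise InfeasibleConfigError("grid too small")


@dataclass
class SyntheticWorld:
    """A generated world plus its analytically known ground truth."""

    config: WorldConfig
    network: RiverNetwork
    grid: FlowGrid
    mines: list[MinePolygon]
    clusters: list[MineCluster]
    pa_sites: list[ConservationSite]
    kba_sites: list[ConservationSite]
    attenuation: AttenuationTable
    #: scenario value -> mine_id -> [(segment_id, start_km, end_km), ...]
    ground_truth: dict[str, dict[str, list[tuple[str, float, float]]]]


def _build_forest(rng: np.random.Generator, rows: int, cols: int,
                  n_basins: int):
    """Randomized multi-source Prim spanning forest, roots on the west edge.

    Returns (parent, basin, visit_order): parent maps cell -> downstream
    cell (None at roots), basin maps cell -> basin index, and
    visit_order lists cells parents-before-children.
    """
    root_rows = np.sort(rng.choice(rows, size=n_basins, replace=False))
    parent: dict[tuple[int, int], Optional[tuple[int, int]]] = {}
    basin: dict[tuple[int, int], int] = {}
    order: list[tuple[int, int]] = []
    heap: list[tuple[float, int, tuple[int, int], Optional[tuple[int, int]]]] = []
    tick = 0
    for b, r in enumerate(root_rows):
        heapq.heappush(heap, (float(rng.random()), tick, (int(r), 0), None))
        tick += 1
    neighbours = list(D8_ESRI.values())
    while heap:
        _, _, cell, from_cell = heapq.heappop(heap)
        if cell in parent:
            continue
        parent[cell] = from_cell
        basin[cell] = basin[from_cell] if from_cell is not None else len(
            {c for c in parent if parent[c] is None}) - 1
        order.append(cell)
        r, c = cell
        for dr, dc in neighbours:
            nr, nc = r + dr, c + dc
            if 0 <= nr < rows and 0 <= nc < cols and (nr, nc) not in parent:
                heapq.heappush(heap, (float(rng.random()), tick,
                                      (nr, nc), cell))
                tick += 1
    return parent, basin, order


def _accumulation(parent, order):
    acc = {cell: 1 for cell in order}
    for cell in reversed(order):
        p = parent[cell]
        if p is not None:
            acc[p] += acc[cell]
    return acc


def _stream_segments(parent, acc, order, stream_frac):
    """Select stream cells and split them into confluence-bounded paths."""
    accs = sorted(acc.values(), reverse=True)
    k = max(1, min(len(accs) - 1, int(round(stream_frac * len(accs)))))
    threshold = accs[k - 1]
    stream = {cell for cell in order if acc[cell] >= threshold}

    children: dict[tuple[int, int], list] = {cell: [] for cell in stream}
    for cell in stream:
        p = parent[cell]
        if p is not None:          # downward-closed: p is in stream too
            children[p].append(cell)
    starts = sorted(cell for cell in stream if len(children[cell]) != 1)
    start_set = set(starts)

    segments = []       # list of cell paths, upstream -> downstream
    for s in starts:
        path = [s]
        cur = s
        while True:
            nxt = parent[cur]
            if nxt is None or nxt in start_set:
                break
            path.append(nxt)
            cur = nxt
        segments.append(path)
    return stream, segments


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Build a complete world: grid, network, mines, sites, ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows, w_cols, cols = config.rows, config.w_cols, config.cols
    cell = config.cell_km
    x_origin, y_origin = 0.0, rows * cell

    def center(rc):
        r, c = rc
        return (x_origin + (c + 0.5) * cell, y_origin - (r + 0.5) * cell)

    parent, basin, order = _build_forest(rng, rows, w_cols, config.n_basins)
    acc = _accumulation(parent, order)
    stream, seg_paths = _stream_segments(parent, acc, order,
                                         config.stream_frac)

    # --- vector network ---------------------------------------------------
    cell_segment: dict[tuple[int, int], int] = {}
    for idx, path in enumerate(seg_paths):
        for rc in path:
            cell_segment[rc] = idx
    seg_ids = [f"S{idx:04d}" for idx in range(len(seg_paths))]
    segments: list[RiverSegment] = []
    for idx, path in enumerate(seg_paths):
        coords = [center(rc) for rc in path]
        tail = parent[path[-1]]
        if tail is not None:
            coords.append(center(tail))
        else:                       # extend a terminal reach out of the sink
            cx, cy = coords[-1]
            coords.append((cx - cell, cy))
        if len(coords) < 2:         # pragma: no cover - paths always >= 1 cell
            continue
        downstream = seg_ids[cell_segment[tail]] if tail is not None else None
        segments.append(RiverSegment(
            segment_id=seg_ids[idx], geometry=LineString(coords),
            downstream_id=downstream, basin_id=f"B{basin[path[0]]}"))

    n_lakes = int(round(config.lake_frac * len(segments)))
    lake_idx = set(rng.choice(len(segments), size=n_lakes, replace=False)
                   ) if n_lakes else set()
    for i, seg in enumerate(segments):
        if i in lake_idx:
            seg.limnicity_pct = float(rng.uniform(
                config.limnicity_threshold + 5.0, 80.0))
        else:
            seg.limnicity_pct = float(rng.uniform(
                0.0, max(config.limnicity_threshold - 5.0, 1.0)))
        seg.discharge_m3s = float(10.0 ** rng.uniform(-1.0, 2.0))
    network = RiverNetwork(segments, mode=config.mode)

    # --- flow grid ---------------------------------------------------------
    direction = np.zeros((rows, cols), dtype=np.int32)
    stream_index = np.full((rows, cols), -1, dtype=np.int32)
    for rc, p in parent.items():
        r, c = rc
        direction[r, c] = 0 if p is None else _CODE_OF[(p[0] - r, p[1] - c)]
    for rc, idx in cell_segment.items():
        stream_index[rc] = idx
    for r in range(rows):
        for c in range(w_cols, cols):
            dr = int(rng.choice([-1, 0, 1], p=[0.2, 0.6, 0.2]))
            if r + dr < 0 or r + dr >= rows:
                dr = 0
            direction[r, c] = _CODE_OF[(dr, -1)]
    grid = FlowGrid(direction=direction, stream_index=stream_index,
                    segment_ids=seg_ids, x_origin=x_origin,
                    y_origin=y_origin, cell_size=cell)

    # --- mines -------------------------------------------------------------
    seg_geoms = [seg.geometry for seg in segments]
    stream_tree = STRtree(seg_geoms)
    stream_cells = sorted(stream)
    stream_centers = np.array([center(rc) for rc in stream_cells])
    max_stream_x = float(stream_centers[:, 0].max())
    n = config.n_mines
    n_far = int(round(config.far_frac * n))
    n_straddle = int(round(config.straddle_frac * n))
    n_near = n - n_far - n_straddle
    kinds = ["straddle"] * n_straddle + ["near"] * n_near + ["far"] * n_far

    areas = np.exp(rng.normal(config.area_lognorm_mu,
                              config.area_lognorm_sigma, size=n))
    areas = np.clip(areas, 0.02, 30.0)
    x_max, y_max = cols * cell, rows * cell

    mines: list[MinePolygon] = []
    for i, kind in enumerate(kinds):
        area = float(areas[i])
        radius = math.sqrt(area / math.pi)
        if kind == "straddle":
            radius = max(radius, 1.35 * cell)
            rc = stream_cells[int(rng.integers(len(stream_cells)))]
            cx, cy = center(rc)
            cx += float(rng.uniform(-0.2, 0.2))
            cy += float(rng.uniform(-0.2, 0.2))
        elif kind == "near":
            radius = min(radius, 2.5 * cell)
            # rejection-sample a centre clear of every stream polyline so
            # the configured straddle fraction stays in control
            cx = cy = None
            for _ in range(20):
                rc = stream_cells[int(rng.integers(len(stream_cells)))]
                sx, sy = center(rc)
                theta = float(rng.uniform(0.0, 2.0 * math.pi))
                dist = radius + float(rng.uniform(0.8, 7.0))
                cand_x = min(max(sx + dist * math.cos(theta), radius + 0.1),
                             x_max - radius - 0.1)
                cand_y = min(max(sy + dist * math.sin(theta), radius + 0.1),
                             y_max - radius - 0.1)
                cx, cy = cand_x, cand_y
                p = Point(cand_x, cand_y)
                nearest = seg_geoms[int(stream_tree.nearest(p))]
                if nearest.distance(p) >= radius + 0.3:
                    break
        else:  # far: beyond the buffer from every stream cell
            radius = min(radius, 1.2)
            lo = max_stream_x + config.buffer_km + 1.5
            hi = x_max - radius - 0.5
            if lo >= hi:
                raise InfeasibleConfigError(
                    "apron too narrow to place a mine beyond the buffer")
            cx = float(rng.uniform(lo, hi))
            cy = float(rng.uniform(1.0, y_max - 1.0))
        if rng.random() < 0.5:
            geom = Point(cx, cy).buffer(radius, quad_segs=8)
        else:
            half = radius * math.sqrt(math.pi) / 2.0
            geom = box(cx - half, cy - half, cx + half, cy + half)
        if rng.random() < config.labeled_frac:
            names = list(config.commodity_freqs)
            probs = np.array([config.commodity_freqs[c] for c in names])
            probs = probs / probs.sum()
            k = 2 if rng.random() < 0.15 else 1
            chosen = rng.choice(names, size=k, replace=False, p=probs)
            commodities = canonicalize_commodities(list(chosen))
        else:
            commodities = frozenset()
        mines.append(MinePolygon(
            mine_id=f"M{i:04d}", cluster_id="", geometry=geom,
            commodities=commodities))

    # --- clusters & planted statuses ----------------------------------------
    n_clusters = max(1, int(round(0.7 * n)))
    assignment = rng.integers(0, n_clusters, size=n)
    status_names = list(config.status_freqs)
    status_probs = np.array([config.status_freqs[s] for s in status_names])
    status_probs = status_probs / status_probs.sum()
    clusters: list[MineCluster] = []
    for ci in range(n_clusters):
        members = [mines[i].mine_id for i in range(n) if assignment[i] == ci]
        planted = str(rng.choice(status_names, p=status_probs))
        clusters.append(MineCluster(
            cluster_id=f"C{ci:04d}", member_ids=members,
            point_statuses=_points_for_status(planted, rng)))
        for i in range(n):
            if assignment[i] == ci:
                mines[i].cluster_id = f"C{ci:04d}"
                mines[i].status = _majority(clusters[-1].point_statuses)

    # --- conservation sites --------------------------------------------------
    pa_sites = [_random_site(rng, f"PA{i:03d}", "PA", config, w_cols * cell,
                             y_max) for i in range(config.n_pa)]
    kba_sites = [_random_site(rng, f"KBA{i:03d}", "KBA", config,
                              w_cols * cell, y_max) for i in range(config.n_kba)]

    attenuation = AttenuationTable(
        element_specific=dict(config.element_distances_km))

    world = SyntheticWorld(
        config=config, network=network, grid=grid, mines=mines,
        clusters=clusters, pa_sites=pa_sites, kba_sites=kba_sites,
        attenuation=attenuation, ground_truth={})
    for scenario in DEFAULT_SCENARIOS:
        world.ground_truth[scenario.value] = {
            mine.mine_id: brute_force_exposure(world, mine, scenario)
            for mine in mines if mine.status != "planned"}
    return world


def _majority(statuses: list[str]) -> str:
    # scalar mode count, used only to plant generator truth
    counts: dict[str, int] = {}
    for s in statuses:
        counts[s] = counts.get(s, 0) + 1
    if not counts:
        return "unknown"
    best = max(counts.values())
    top = [s for s, c in counts.items() if c == best]
    return top[0] if len(top) == 1 else "unknown"


def _points_for_status(planted: str, rng: np.random.Generator) -> list[str]:
    """A property-point status multiset whose majority is ``planted``."""
    if planted == "unknown":
        r = rng.random()
        if r < 0.4:
            return []
        if r < 0.7:
            return ["active", "inactive"]          # tie -> unknown
        return ["unknown"]
    k = int(rng.integers(1, 4))
    pts = [planted] * k
    others = [s for s in ("active", "inactive", "unknown") if s != planted]
    m = int(rng.integers(0, k))                    # strictly fewer than k
    pts += [str(s) for s in rng.choice(others, size=m)]
    return pts


def _random_site(rng: np.random.Generator, site_id: str, layer: str,
                 config: WorldConfig, x_extent: float,
                 y_extent: float) -> ConservationSite:
    cx = float(rng.uniform(2.0, x_extent - 2.0))
    cy = float(rng.uniform(2.0, y_extent - 2.0))
    is_point = rng.random() < config.point_site_frac
    if is_point:
        geometry = Point(cx, cy)
        area = float(rng.uniform(5.0, 60.0))
    else:
        w = float(rng.uniform(3.0, 12.0))
        h = float(rng.uniform(3.0, 12.0))
        geometry = box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
        area = w * h
    if layer == "PA":
        designation = str(rng.choice(["national", "international",
                                      "supplementary"], p=[0.7, 0.15, 0.15]))
        iucn = rng.choice(np.array(["", "Ia", "II", "III", "IV", "VI"],
                                   dtype=object),
                          p=[0.3, 0.1, 0.25, 0.1, 0.2, 0.05])
        iucn_category = str(iucn) or None
        status_flag = "proposed" if rng.random() < 0.1 else "designated"
        marine = bool(rng.random() < 0.05) if is_point else False
    else:
        designation, iucn_category = "international", None
        status_flag, marine = "designated", False
    return ConservationSite(
        site_id=site_id, layer=layer, geometry=geometry,
        reported_area_km2=area, designation_type=designation,
        iucn_category=iucn_category, status_flag=status_flag, marine=marine)


# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------

def _budget_walk(network: RiverNetwork, sid: str, offset: float,
                 budget: float, threshold: float,
                 out: list[tuple[str, float, float]]) -> None:
    seg = network[sid]
    if seg.limnicity_pct > threshold:
        return
    end = min(seg.length_km, offset + budget)
    if end > offset + 1e-12:
        out.append((sid, offset, end))
        budget -= end - offset
    if budget > 1e-12 and end >= seg.length_km - 1e-12 \
            and seg.downstream_id is not None \
            and seg.downstream_id in network.segments:
        _budget_walk(network, seg.downstream_id, 0.0, budget, threshold, out)


def brute_force_exposure(world: SyntheticWorld, mine: MinePolygon,
                         scenario: Scenario
                         ) -> list[tuple[str, float, float]]:
    """Re-derive one mine's exposure with plain scalar recursion.

    Walks the D8 array directly, applies the straight-line buffer rule,
    clips the mine polygon against every segment, and recursively spends
    the attenuation budget downstream.  Shares no tracing or interval
    code with the pipeline; used only as a test oracle.
    """
    net, grid, cfg = world.network, world.grid, world.config
    distance = resolve_distance(mine.commodities, world.attenuation, scenario)
    out: list[tuple[str, float, float]] = []

    geom = mine.geometry
    if geom.geom_type == "MultiPolygon":
        geom = max(geom.geoms, key=lambda g: g.area)
    p = geom.representative_point()
    loc = grid.cell_of(p.x, p.y)
    nrow, ncol = grid.shape
    steps = 0
    while loc is not None and steps <= nrow * ncol:
        r, c = loc
        idx = int(grid.stream_index[r, c])
        if idx >= 0:
            cx, cy = grid.center_of(r, c)
            if math.hypot(cx - p.x, cy - p.y) <= cfg.buffer_km:
                sid = grid.segment_ids[idx]
                seg = net[sid]
                frac = seg.geometry.project(Point(cx, cy), normalized=True)
                _budget_walk(net, sid, frac * seg.length_km, distance,
                             cfg.limnicity_threshold, out)
            break
        code = int(grid.direction[r, c])
        if code == grid.sink_code or code not in grid.codes:
            break
        dr, dc = grid.codes[code]
        r, c = r + dr, c + dc
        loc = (r, c) if 0 <= r < nrow and 0 <= c < ncol else None
        steps += 1

    for sid, seg in net.segments.items():
        if not seg.geometry.intersects(mine.geometry):
            continue
        clipped = seg.geometry.intersection(mine.geometry)
        parts = [clipped] if clipped.geom_type == "LineString" else [
            g for g in getattr(clipped, "geoms", []) if
            g.geom_type == "LineString"]
        for part in parts:
            f0 = seg.geometry.project(Point(part.coords[0]), normalized=True)
            f1 = seg.geometry.project(Point(part.coords[-1]), normalized=True)
            a, b = sorted((f0 * seg.length_km, f1 * seg.length_km))
            if b - a < 1e-9:
                continue
            out.append((sid, a, b))
            _budget_walk(net, sid, b, distance, cfg.limnicity_threshold, out)
    return sorted(out)
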