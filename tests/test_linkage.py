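"""Entry-point location: interior points, D8 routing, intersections."""

import warnings

import numpy as np
import pytest
from shapely.geometry import LineString, MultiPolygon, Point, Polygon, box

from minetrace.hydrography import FlowGrid, RiverNetwork, RiverSegment
from minetrace.linkage import (OutsideGridError, interior_point,
                               intersect_rivers, link_mine, route_downslope,
                               validate_random_sampling)
from minetrace.mines import MinePolygon

from conftest import chain_network


def _south_draining_grid(rows=13, cols=6):
    """One west-east stream along the bottom row; everything drains south."""
    seg = RiverSegment("A", LineString([(0.5, 0.5), (cols - 0.5, 0.5)]),
                       basin_id="B")
    net = RiverNetwork([seg])
    direction = np.full((rows, cols), 4, dtype=np.int32)   # S
    stream_index = np.full((rows, cols), -1, dtype=np.int32)
    stream_index[rows - 1, :] = 0
    direction[rows - 1, :-1] = 1                           # E along stream
    direction[rows - 1, -1] = 0                            # sink
    grid = FlowGrid(direction=direction, stream_index=stream_index,
                    segment_ids=["A"], x_origin=0.0, y_origin=float(rows),
                    cell_size=1.0)
    return grid, net


class TestInteriorPoint:
    def test_unit_square(self):
        poly = box(0, 0, 1, 1)
        assert poly.contains(interior_point(poly))

    def test_c_shape_whose_centroid_is_outside(self):
        c_shape = Polygon([(0, 0), (4, 0), (4, 1), (1, 1), (1, 3), (4, 3),
                           (4, 4), (0, 4)])
        point = interior_point(c_shape)
        assert c_shape.contains(point)

    def test_multipolygon_uses_largest_part(self):
        small, big = box(0, 0, 1, 1), box(5, 5, 8, 8)
        point = interior_point(MultiPolygon([small, big]))
        assert big.contains(point) and not small.contains(point)

    def test_empty_geometry_rejected(self):
        with pytest.raises(ValueError):
            interior_point(Polygon())


class TestRouteDownslope:
    def test_point_on_stream_cell_is_immediate(self):
        grid, net = _south_draining_grid()
        entry = route_downslope(Point(2.5, 0.5), grid, net)
        assert entry.segment_id == "A"
        assert entry.offset_km == pytest.approx(2.0)
        assert entry.geodesic_distance_km == pytest.approx(0.0)

    def test_hand_walked_five_cell_path(self):
        grid, net = _south_draining_grid()
        entry = route_downslope(Point(2.5, 5.5), grid, net)
        assert entry.segment_id == "A"
        assert entry.offset_km == pytest.approx(2.0)
        assert entry.geodesic_distance_km == pytest.approx(5.0)

    def test_beyond_buffer_excluded(self):
        grid, net = _south_draining_grid(rows=13)
        assert route_downslope(Point(2.5, 12.5), grid, net,
                               max_km=10.0) is None
        # but reachable with a wider buffer
        assert route_downslope(Point(2.5, 12.5), grid, net,
                               max_km=15.0) is not None

    def test_sink_code_returns_none(self):
        grid, net = _south_draining_grid()
        grid.direction[5, 2] = 0
        assert route_downslope(Point(2.5, 7.5), grid, net) is None

    def test_walk_exiting_grid_returns_none(self):
        grid, net = _south_draining_grid()
        grid.direction[5, 2] = 16      # W, marches off the west edge
        grid.direction[5, 1] = 16
        grid.direction[5, 0] = 16
        assert route_downslope(Point(2.5, 7.5), grid, net) is None

    def test_outside_extent_raises(self):
        grid, net = _south_draining_grid()
        with pytest.raises(OutsideGridError):
            route_downslope(Point(-5.0, 2.0), grid, net)

    def test_deterministic(self):
        grid, net = _south_draining_grid()
        a = route_downslope(Point(3.3, 8.9), grid, net)
        b = route_downslope(Point(3.3, 8.9), grid, net)
        assert a == b

    def test_loop_guard_warns_and_returns_none(self):
        grid, net = _south_draining_grid()
        grid.direction[5, 2] = 1       # E
        grid.direction[5, 3] = 16      # W -> two-cell loop
        with pytest.warns(UserWarning):
            assert route_downslope(Point(2.5, 7.5), grid, net) is None


class TestIntersectRivers:
    def test_disjoint_mine_yields_empty(self):
        net = chain_network([5.0])
        mine = MinePolygon("M", "C", box(10, 10, 11, 11))
        direct = intersect_rivers(mine, net)
        assert direct.intervals == [] and direct.exit_points == []

    def test_square_clipping_straight_segment(self):
        net = chain_network([5.0])     # A from (0,0) to (5,0)
        mine = MinePolygon("M", "C", box(1, -1, 2, 1))
        direct = intersect_rivers(mine, net)
        (iv,) = direct.intervals
        assert (iv.segment_id, iv.start_km, iv.end_km) == ("A", 1.0, 2.0)
        (exit_point,) = direct.exit_points
        assert exit_point.offset_km == pytest.approx(2.0)
        assert exit_point.method == "intersection_exit"

    def test_mine_over_confluence(self):
        segs = [
            RiverSegment("A", LineString([(0, 0), (2, 0)]), "C", basin_id="B"),
            RiverSegment("B", LineString([(2, 2), (2, 0)]), "C", basin_id="B"),
            RiverSegment("C", LineString([(2, 0), (5, 0)]), None,
                         basin_id="B"),
        ]
        net = RiverNetwork(segs)
        mine = MinePolygon("M", "CL", box(1.5, -0.5, 3, 1.5))
        direct = intersect_rivers(mine, net)
        got = {(iv.segment_id, round(iv.start_km, 9), round(iv.end_km, 9))
               for iv in direct.intervals}
        assert got == {("A", 1.5, 2.0), ("B", 0.5, 2.0), ("C", 0.0, 1.0)}
        exits_on_c = [e for e in direct.exit_points if e.segment_id == "C"]
        assert exits_on_c[0].offset_km == pytest.approx(1.0)

    def test_interval_lengths_match_clipped_geometry(self, small_world):
        """Sum of interval lengths equals the length of the clipped lines."""
        net = small_world.network
        for mine in small_world.mines:
            direct = intersect_rivers(mine, net)
            interval_total = sum(iv.length_km for iv in direct.intervals)
            clip_total = sum(
                net[s].geometry.intersection(mine.geometry).length
                for s in net.segments
                if net[s].geometry.intersects(mine.geometry))
            assert interval_total == pytest.approx(clip_total, rel=1e-6,
                                                   abs=1e-9)


class TestRandomSampling:
    def test_single_hillslope_agrees_fully(self):
        grid, net = _south_draining_grid()
        mine = MinePolygon("M", "C", box(1.2, 3.2, 4.8, 6.8))
        assert validate_random_sampling(mine, grid, net, n_points=30,
                                        seed=7) == pytest.approx(1.0)

    def test_drainage_divide_lowers_agreement(self):
        # two separate sink streams, west and east; divide at x = 3
        segs = [RiverSegment("L", LineString([(0.5, 0.5), (0.5, 5.5)]),
                             basin_id="B1"),
                RiverSegment("R", LineString([(5.5, 0.5), (5.5, 5.5)]),
                             basin_id="B2")]
        net = RiverNetwork(segs)
        direction = np.full((6, 6), 16, dtype=np.int32)    # W
        direction[:, 3:] = 1                               # E
        stream_index = np.full((6, 6), -1, dtype=np.int32)
        stream_index[:, 0] = 0
        stream_index[:, 5] = 1
        grid = FlowGrid(direction=direction, stream_index=stream_index,
                        segment_ids=["L", "R"], x_origin=0.0, y_origin=6.0,
                        cell_size=1.0)
        mine = MinePolygon("M", "C", box(1.2, 1.2, 4.8, 4.8))
        agreement = validate_random_sampling(mine, grid, net, n_points=40,
                                             seed=3)
        assert 0.0 < agreement < 1.0

    def test_seeded_repeatability(self, small_world):
        mine = small_world.mines[0]
        kwargs = dict(n_points=5, seed=123)
        a = validate_random_sampling(mine, small_world.grid,
                                     small_world.network, **kwargs)
        b = validate_random_sampling(mine, small_world.grid,
                                     small_world.network, **kwargs)
        assert a == b


def test_routing_never_loops_on_generated_worlds():
    """The generator's D8 fields are loop-free: the guard never fires."""
    from minetrace.synthetic import WorldConfig, generate_world
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        for seed in range(10):
            world = generate_world(WorldConfig(seed=seed, rows=16, w_cols=16,
                                               apron_cols=8, n_mines=6,
                                               n_pa=2, n_kba=1))
            for mine in world.mines:
                link_mine(mine, world.grid, world.network)


def test_centroid_entries_respect_buffer(small_world):
    for mine in small_world.mines:
        entry = link_mine(mine, small_world.grid, small_world.network,
                          max_km=10.0)
        if entry is not None:
            assert entry.geodesic_distance_km <= 10.0
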