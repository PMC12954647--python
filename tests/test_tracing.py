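"""Downstream propagation, dissolve, and length accounting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from shapely.geometry import box

from minetrace.attenuation import Scenario
from minetrace.hydrography import SegmentInterval
from minetrace.linkage import DirectExposure, EntryPoint
from minetrace.mines import MinePolygon
from minetrace.tracing import (ExposedReach, ExposureSet, contains, dissolve,
                               total_length, trace_downstream, trace_mine)

from conftest import chain_network


def _spans(intervals):
    return [(iv.segment_id, iv.start_km, iv.end_km) for iv in intervals]


class TestTraceDownstream:
    def test_budget_split_across_segments(self):
        """Entry at km 2 of a 5 km reach, 6.5 km budget: 3 + 3.5 km."""
        net = chain_network([5.0, 4.0, 10.0])
        out = trace_downstream(net, "A", 2.0, 6.5)
        assert _spans(out) == [("A", 2.0, 5.0), ("B", 0.0, 3.5)]
        assert sum(iv.length_km for iv in out) == pytest.approx(6.5)

    def test_zero_distance_is_empty(self):
        net = chain_network([5.0])
        assert trace_downstream(net, "A", 2.0, 0.0) == []

    def test_lentic_stop_before_segment(self):
        net = chain_network([3.0, 5.0, 10.0], limnicities=[0.0, 30.0, 0.0])
        out = trace_downstream(net, "A", 0.0, 45.6)
        assert _spans(out) == [("A", 0.0, 3.0)]

    def test_lentic_entry_segment_yields_nothing(self):
        net = chain_network([3.0, 5.0], limnicities=[30.0, 0.0])
        assert trace_downstream(net, "A", 1.0, 45.6) == []

    def test_sink_truncates(self):
        net = chain_network([2.0])
        out = trace_downstream(net, "A", 0.0, 45.6)
        assert _spans(out) == [("A", 0.0, 2.0)]

    def test_entry_at_downstream_node_continues_below(self):
        net = chain_network([5.0, 4.0])
        out = trace_downstream(net, "A", 5.0, 2.0)
        assert _spans(out) == [("B", 0.0, 2.0)]

    def test_unknown_segment_raises(self):
        net = chain_network([5.0])
        from minetrace.hydrography import NetworkError
        with pytest.raises(NetworkError):
            trace_downstream(net, "NOPE", 0.0, 1.0)

    @given(st.floats(0.0, 5.0), st.floats(0.0, 60.0))
    def test_traced_total_never_exceeds_budget(self, offset, distance):
        net = chain_network([5.0, 4.0, 10.0, 7.0])
        out = trace_downstream(net, "A", offset, distance)
        total = sum(iv.length_km for iv in out)
        assert total <= distance + 1e-9
        # equality when the path below the entry is long enough
        path_capacity = (5.0 - offset) + 4.0 + 10.0 + 7.0
        if distance <= path_capacity:
            assert total == pytest.approx(distance, abs=1e-9)


class TestTraceMine:
    def _mine(self, commodities=frozenset({"gold"})):
        return MinePolygon("M1", "C", box(0, 5, 1, 6),
                           commodities=commodities, status="active")

    def test_entry_only_matches_trace_downstream(self):
        net = chain_network([5.0, 4.0])
        entry = EntryPoint("M1", "A", 2.0, "centroid")
        reaches = trace_mine(net, self._mine(), entry, None, 6.5)
        assert _spans(r.interval for r in reaches) == _spans(
            trace_downstream(net, "A", 2.0, 6.5))
        assert all(r.sources == frozenset({"M1"}) for r in reaches)
        assert all(r.statuses == frozenset({"active"}) for r in reaches)

    def test_direct_interval_plus_exit_trace(self):
        net = chain_network([5.0, 4.0])
        direct = DirectExposure(
            "M1", intervals=[SegmentInterval("A", 1.0, 2.0)],
            exit_points=[EntryPoint("M1", "A", 2.0, "intersection_exit")])
        reaches = trace_mine(net, self._mine(), None, direct, 3.0)
        spans = _spans(r.interval for r in reaches)
        assert ("A", 1.0, 2.0) in spans          # in-mine, verbatim
        assert ("A", 2.0, 5.0) in spans          # 3 km onward from the exit
        direct_flags = {(r.interval.start_km, r.direct) for r in reaches}
        assert (1.0, True) in direct_flags

    def test_exit_budget_restarts_at_zero(self):
        """The in-mine interval does not consume attenuation budget."""
        net = chain_network([5.0, 4.0])
        direct = DirectExposure(
            "M1", intervals=[SegmentInterval("A", 0.0, 4.0)],
            exit_points=[EntryPoint("M1", "A", 4.0, "intersection_exit")])
        reaches = trace_mine(net, self._mine(), None, direct, 3.0)
        traced = [r for r in reaches if not r.direct]
        assert sum(r.interval.length_km for r in traced) == pytest.approx(3.0)

    def test_overlapping_methods_retained_before_dissolve(self):
        net = chain_network([5.0])
        entry = EntryPoint("M1", "A", 1.0, "centroid")
        direct = DirectExposure(
            "M1", intervals=[SegmentInterval("A", 0.5, 2.0)],
            exit_points=[EntryPoint("M1", "A", 2.0, "intersection_exit")])
        reaches = trace_mine(net, self._mine(), entry, direct, 2.0)
        assert len(reaches) == 3                 # overlaps kept

    def test_nothing_without_entry_or_direct(self):
        net = chain_network([5.0])
        assert trace_mine(net, self._mine(), None, None, 10.0) == []
        assert trace_mine(net, self._mine(), None,
                          DirectExposure("M1"), 10.0) == []


def _reach(sid, a, b, mine="M1", direct=False, commodities=("gold",),
           status="active"):
    return ExposedReach(interval=SegmentInterval(sid, a, b),
                        sources=frozenset({mine}),
                        commodities=frozenset(commodities),
                        statuses=frozenset({status}), direct=direct)


class TestDissolve:
    def test_overlapping_intervals_merge_and_union_sources(self):
        exposure = ExposureSet(reaches=[
            _reach("A", 0.0, 3.0, mine="M1"),
            _reach("A", 2.0, 5.0, mine="M2", commodities=("copper",),
                   status="inactive")])
        (merged,) = dissolve(exposure).reaches
        assert (merged.interval.start_km, merged.interval.end_km) == (0.0, 5.0)
        assert merged.sources == frozenset({"M1", "M2"})
        assert merged.commodities == frozenset({"gold", "copper"})
        assert merged.statuses == frozenset({"active", "inactive"})

    def test_adjacent_intervals_merge_at_shared_endpoint(self):
        exposure = ExposureSet(reaches=[_reach("A", 0.0, 2.0),
                                        _reach("A", 2.0, 3.0)])
        assert len(dissolve(exposure).reaches) == 1

    def test_disjoint_intervals_untouched(self):
        exposure = ExposureSet(reaches=[_reach("A", 0.0, 1.0),
                                        _reach("A", 2.0, 3.0)])
        out = dissolve(exposure).reaches
        assert _spans(r.interval for r in out) == [("A", 0.0, 1.0),
                                                   ("A", 2.0, 3.0)]

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        reaches = [_reach("A", a, a + w)
                   for a, w in zip(rng.uniform(0, 90, 60),
                                   rng.uniform(0.01, 10, 60))]
        once = dissolve(ExposureSet(reaches=reaches))
        twice = dissolve(once)
        assert _spans(r.interval for r in once.reaches) == _spans(
            r.interval for r in twice.reaches)

    def test_random_union_against_metre_discretization(self):
        """Dissolved length equals a 1 m discretization oracle (+-1 m)."""
        rng = np.random.default_rng(99)
        starts = rng.uniform(0, 99, 100)
        widths = rng.uniform(0.001, 20, 100)
        reaches = [_reach("A", a, min(a + w, 100.0))
                   for a, w in zip(starts, widths)]
        dissolved = dissolve(ExposureSet(reaches=reaches))
        got = total_length(dissolved)
        cells = np.zeros(100_000, dtype=bool)   # 1 m bins over 100 km
        for r in reaches:
            # a bin counts as covered iff its midpoint is covered
            lo = int(np.ceil(r.interval.start_km * 1000 - 0.5))
            hi = int(np.floor(r.interval.end_km * 1000 - 0.5)) + 1
            cells[max(lo, 0):hi] = True
        assert abs(got - cells.sum() / 1000.0) <= 1e-3

    def test_total_never_exceeds_input_sum(self):
        rng = np.random.default_rng(5)
        reaches = [_reach("A", a, a + w)
                   for a, w in zip(rng.uniform(0, 50, 30),
                                   rng.uniform(0.1, 5, 30))]
        exposure = ExposureSet(reaches=reaches)
        assert total_length(dissolve(exposure)) <= total_length(exposure)


class TestTotalLength:
    def test_unweighted_simple(self):
        assert total_length(ExposureSet(reaches=[_reach("A", 0.0, 5.0)])) \
            == pytest.approx(5.0)
        assert total_length(ExposureSet(reaches=[])) == 0.0

    def test_copper_demand_scaling(self):
        reach = _reach("A", 0.0, 1000.0, commodities=("copper",))
        got = total_length([reach], weights={"M1": 0.2441})
        assert got == pytest.approx(244.1)

    def test_weighted_capped_by_union(self):
        # two mines fully overlapping with weights summing above 1
        reaches = [_reach("A", 0.0, 10.0, mine="M1"),
                   _reach("A", 0.0, 10.0, mine="M2")]
        got = total_length(reaches, weights={"M1": 0.6, "M2": 0.6})
        assert got == pytest.approx(10.0)       # capped at dissolved length

    def test_within_mine_overlap_not_double_counted(self):
        reaches = [_reach("A", 0.0, 6.0, mine="M1"),
                   _reach("A", 4.0, 10.0, mine="M1")]
        got = total_length(reaches, weights={"M1": 0.5})
        assert got == pytest.approx(5.0)        # 0.5 x union(10), not x 12

    def test_weighted_mode_rejects_merged_sources(self):
        merged = ExposedReach(interval=SegmentInterval("A", 0.0, 1.0),
                              sources=frozenset({"M1", "M2"}))
        with pytest.raises(ValueError):
            total_length([merged], weights={"M1": 0.5, "M2": 0.5})


def test_scenario_containment_on_chain():
    net = chain_network([5.0, 4.0, 10.0, 7.0])
    short = ExposureSet(reaches=[
        _reach(*iv_args) for iv_args in
        [(iv.segment_id, iv.start_km, iv.end_km)
         for iv in trace_downstream(net, "A", 1.0, 6.5)]],
        scenario=Scenario.MODERATE)
    long = ExposureSet(reaches=[
        _reach(iv.segment_id, iv.start_km, iv.end_km)
        for iv in trace_downstream(net, "A", 1.0, 45.6)],
        scenario=Scenario.SEVERE)
    assert contains(long, short)
    assert not contains(short, long)
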