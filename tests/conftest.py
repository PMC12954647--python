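from __future__ import annotations

import pytest
from hypothesis import settings
from shapely.geometry import LineString

from minetrace.hydrography import RiverNetwork, RiverSegment
from minetrace.synthetic import WorldConfig, generate_world

import worlds

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

#: world size used across randomized tests (kept small for exactness speed)
SMALL_WORLD = dict(rows=32, w_cols=32, apron_cols=16, n_mines=12,
                   n_pa=4, n_kba=3)


def chain_network(lengths, limnicities=None, mode="planar") -> RiverNetwork:
    """A straight west-east chain A -> B -> C ... with given km lengths."""
    limnicities = limnicities or [0.0] * len(lengths)
    ids = [chr(ord("A") + i) for i in range(len(lengths))]
    segments, x = [], 0.0
    for i, (length, limn) in enumerate(zip(lengths, limnicities)):
        geometry = LineString([(x, 0.0), (x + length, 0.0)])
        down = ids[i + 1] if i + 1 < len(ids) else None
        segments.append(RiverSegment(segment_id=ids[i], geometry=geometry,
                                     downstream_id=down, limnicity_pct=limn,
                                     basin_id="B"))
        x += length
    return RiverNetwork(segments, mode=mode)


@pytest.fixture(scope="session")
def small_world():
    return generate_world(WorldConfig(seed=11, **SMALL_WORLD))


@pytest.fixture(scope="session")
def planted_world():
    return worlds.build_planted_world()
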