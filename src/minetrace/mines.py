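"""Mine polygons: status harmonization, commodities, demand shares.

Mining land-use polygons arrive grouped into clusters that were matched
to mine-property points carrying raw operational statuses.  Statuses are
harmonized to four categories (active / inactive / planned / unknown) by
a majority rule over the property points of each cluster; ties of any
multiplicity resolve to unknown.  Planned mines are excluded from the
exposure analysis.

Energy-transition minerals (ETMs) are copper, lithium, nickel, cobalt,
graphite and rare earth elements; their clean-energy demand shares (IEA
2023 estimates) scale exposed river lengths to the portion attributable
to clean-energy demand.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from shapely.geometry import MultiPolygon, Polygon
from shapely.validation import make_valid

log = logging.getLogger(__name__)

STATUSES = ("active", "inactive", "planned", "unknown")

ETM_COMMODITIES = frozenset({
    "copper", "lithium", "nickel", "cobalt", "graphite",
    "rare earth elements",
})

#: IEA 2023 clean-energy demand shares per ETM (fraction of total demand).
DEFAULT_DEMAND_SHARES: dict[str, float] = {
    "copper": 0.2441,
    "lithium": 0.5576,
    "nickel": 0.1540,
    "cobalt": 0.2977,
    "graphite": 0.2789,
    "rare earth elements": 0.1720,
}

#: Raw status strings -> harmonized category.  Extend via config.
DEFAULT_STATUS_MAP: dict[str, str] = {
    "active": "active",
    "operating": "active",
    "in operation": "active",
    "production": "active",
    "inactive": "inactive",
    "closed": "inactive",
    "abandoned": "inactive",
    "care and maintenance": "inactive",
    "suspended": "inactive",
    "planned": "planned",
    "proposed": "planned",
    "construction planned": "planned",
    "unknown": "unknown",
    "uncertain": "unknown",
    "": "unknown",
}

#: Commodity synonyms -> canonical names.  Extend via config.
DEFAULT_COMMODITY_SYNONYMS: dict[str, str] = {
    "cu": "copper",
    "li": "lithium",
    "ni": "nickel",
    "co": "cobalt",
    "ree": "rare earth elements",
    "rare earths": "rare earth elements",
    "rare earth": "rare earth elements",
    "au": "gold",
    "ag": "silver",
    "fe": "iron",
    "iron ore": "iron",
    "zn": "zinc",
    "pb": "lead",
}


class ConfigGapError(KeyError):
    """A raw attribute value has no mapping in the supplied config."""


@dataclass
class MinePolygon:
    """A mining land-use footprint with harmonized attributes.

    An empty ``commodities`` set means the primary commodity is unknown.
    ``area_km2`` is derived from the geometry (planar mode: coordinates
    in km).
    """

    mine_id: str
    cluster_id: str
    geometry: Polygon | MultiPolygon
    commodities: frozenset[str] = frozenset()
    status: str = "unknown"
    area_km2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"status {self.status!r} not in {STATUSES}")
        if not self.geometry.is_valid:
            self.geometry = make_valid(self.geometry)
        if self.area_km2 is None:
            self.area_km2 = float(self.geometry.area)


@dataclass
class MineCluster:
    """A cluster of mine polygons matched to property points."""

    cluster_id: str
    member_ids: list[str] = field(default_factory=list)
    point_statuses: list[str] = field(default_factory=list)


@dataclass
class DemandShareTable:
    """ETM commodity -> clean-energy demand fraction for a reference year."""

    shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEMAND_SHARES))
    year: int = 2023

    def __post_init__(self) -> None:
        for name, frac in self.shares.items():
            if not (0.0 < frac <= 1.0):
                raise ValueError(f"demand share for {name} out of (0, 1]: {frac}")


def map_raw_status(raw: str,
                   status_map: Mapping[str, str] = DEFAULT_STATUS_MAP) -> str:
    key = raw.strip().lower()
    try:
        return status_map[key]
    except KeyError:
        raise ConfigGapError(f"raw status {raw!r} has no mapping") from None


def canonicalize_commodities(
        raw: str | Sequence[str],
        synonyms: Mapping[str, str] = DEFAULT_COMMODITY_SYNONYMS,
        delimiter: str = ",") -> frozenset[str]:
    """Parse and canonicalize a commodity list; empty input -> empty set."""
    if isinstance(raw, str):
        items = raw.split(delimiter)
    else:
        items = list(raw)
    out = set()
    for item in items:
        name = item.strip().lower()
        if not name:
            continue
        out.add(synonyms.get(name, name))
    return frozenset(out)


def harmonize_status(cluster: MineCluster) -> str:
    """Majority status over a cluster's property points.

    Returns the strictly most frequent harmonized status; any tie for
    the top count (and the empty multiset) yields ``"unknown"``.
    """
    counts = Counter(cluster.point_statuses)
    for status in counts:
        if status not in STATUSES:
            raise ConfigGapError(
                f"status {status!r} not harmonized before majority rule")
    if not counts:
        return "unknown"
    ranked = counts.most_common()
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return "unknown"
    return ranked[0][0]


def apply_cluster_statuses(mines: Iterable[MinePolygon],
                           clusters: Iterable[MineCluster]) -> list[MinePolygon]:
    """Assign each mine the majority status of its cluster (in place)."""
    by_cluster = {c.cluster_id: harmonize_status(c) for c in clusters}
    mines = list(mines)
    for mine in mines:
        mine.status = by_cluster.get(mine.cluster_id, "unknown")
    return mines


def exclude_planned(mines: Iterable[MinePolygon]
                    ) -> tuple[list[MinePolygon], int]:
    """Drop mines with harmonized status ``planned``; report the count."""
    mines = list(mines)
    kept = [m for m in mines if m.status != "planned"]
    removed = len(mines) - len(kept)
    if not kept and mines:
        log.warning("all %d mines were planned; nothing left to analyse",
                    len(mines))
    return kept, removed


def is_key_etm(commodities: frozenset[str] | set[str]) -> bool:
    """True iff the commodity set intersects the key-ETM list."""
    return bool(ETM_COMMODITIES & set(commodities))


def demand_share(commodities: frozenset[str] | set[str],
                 table: DemandShareTable) -> float:
    """Mean clean-energy demand fraction over a mine's ETM commodities.

    Non-ETM members are ignored; a set with no ETM member is a misuse
    and raises ``ValueError``.
    """
    etms = sorted(ETM_COMMODITIES & set(commodities))
    if not etms:
        raise ValueError("demand_share needs at least one ETM commodity")
    return sum(table.shares[c] for c in etms) / len(etms)
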