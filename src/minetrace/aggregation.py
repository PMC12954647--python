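"""Summary statistics: exposed length and proportion per reporting unit.

Units are the global network, commodity groups (with the key-ETM group),
main basins, activity-status classes, conservation sites, and the CPA
union itself.  The proportion is exposed length divided by total river
length within the unit.  River stretches affected by several commodities
or statuses are counted under each matching group (multi-counting), so
group rows are deliberately not additive; basin rows, by contrast,
partition the global total exactly because every segment belongs to one
basin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .attenuation import Scenario
from .conservation import CPALayer, overlay_lengths
from .hydrography import RiverNetwork, interval_geometry
from .mines import DemandShareTable, demand_share, is_key_etm
from .tracing import (ExposedReach, ExposureSet, dissolve, total_length)

UNKNOWN_COMMODITY = "unknown"
KEY_ETM_GROUP = "key_etm"


@dataclass
class ExposureSummary:
    """Exposed vs. total river length for one reporting unit."""

    unit_kind: str   # global | commodity | basin | site | status | cpa
    unit_id: str
    scenario: Scenario
    exposed_km: float
    total_km: float
    clean_energy_km: Optional[float] = None

    @property
    def proportion(self) -> float:
        return self.exposed_km / self.total_km if self.total_km > 0 else 0.0


def _reach_commodity_labels(reach: ExposedReach) -> frozenset[str]:
    return reach.commodities if reach.commodities else frozenset(
        {UNKNOWN_COMMODITY})


def _exposed_in_cpa(reaches: Iterable[ExposedReach], network: RiverNetwork,
                    cpa: CPALayer, mode: str) -> float:
    lines = [interval_geometry(network, r.interval) for r in reaches]
    return overlay_lengths(lines, cpa, mode=mode).inside_km


def summarize_global(exposure: ExposureSet, network: RiverNetwork
                     ) -> ExposureSummary:
    """Dissolved exposed length against the whole network."""
    dissolved = exposure if exposure.dissolved else dissolve(exposure)
    return ExposureSummary(
        unit_kind="global", unit_id="global", scenario=exposure.scenario,
        exposed_km=total_length(dissolved),
        total_km=network.total_length_km())


def summarize_by_commodity(per_mine_reaches: Iterable[ExposedReach],
                           network: RiverNetwork,
                           scenario: Scenario,
                           cpa: Optional[CPALayer] = None,
                           mode: str = "planar") -> list[ExposureSummary]:
    """One row per commodity plus the key-ETM group.

    Expects per-mine reaches (before the cross-mine dissolve); each
    group is dissolved internally.  Multi-commodity reaches contribute
    to every matching row.  With a CPA layer, exposed and total lengths
    are clipped to it.
    """
    reaches = list(per_mine_reaches)
    groups: dict[str, list[ExposedReach]] = {}
    for reach in reaches:
        for name in _reach_commodity_labels(reach):
            groups.setdefault(name, []).append(reach)
        if is_key_etm(reach.commodities):
            groups.setdefault(KEY_ETM_GROUP, []).append(reach)
    if cpa is None:
        denominator = network.total_length_km()
    else:
        denominator = overlay_lengths(
            (network[s].geometry for s in network.segments), cpa,
            mode=mode).inside_km
    rows = []
    for name in sorted(groups):
        dissolved = dissolve(ExposureSet(reaches=groups[name],
                                         scenario=scenario))
        if cpa is None:
            exposed = total_length(dissolved)
        else:
            exposed = _exposed_in_cpa(dissolved.reaches, network, cpa, mode)
        rows.append(ExposureSummary(
            unit_kind="commodity", unit_id=name, scenario=scenario,
            exposed_km=exposed, total_km=denominator))
    return rows


def summarize_by_basin(exposure: ExposureSet, network: RiverNetwork
                       ) -> list[ExposureSummary]:
    """Exposed and total length per main basin (exact partition)."""
    dissolved = exposure if exposure.dissolved else dissolve(exposure)
    basin_totals = network.basin_lengths_km()
    exposed: dict[str, float] = {b: 0.0 for b in basin_totals}
    for reach in dissolved.reaches:
        basin = network[reach.interval.segment_id].basin_id
        exposed[basin] += reach.interval.length_km
    return [ExposureSummary(unit_kind="basin", unit_id=basin,
                            scenario=exposure.scenario,
                            exposed_km=exposed[basin],
                            total_km=basin_totals[basin])
            for basin in sorted(basin_totals)]


def summarize_by_status(per_mine_reaches: Iterable[ExposedReach],
                        network: RiverNetwork, scenario: Scenario,
                        multi_count: bool = True) -> list[ExposureSummary]:
    """Dissolved exposed length per activity-status class.

    ``multi_count=True`` (default) counts a reach under every status of
    its source mines, mirroring the commodity rule.  The exclusive mode
    assigns reaches touched by several statuses to a ``"multiple"`` row
    instead, making rows additive.
    """
    reaches = list(per_mine_reaches)
    groups: dict[str, list[ExposedReach]] = {}
    for reach in reaches:
        statuses = sorted(reach.statuses) or ["unknown"]
        if multi_count or len(statuses) == 1:
            for status in statuses:
                groups.setdefault(status, []).append(reach)
        else:
            groups.setdefault("multiple", []).append(reach)
    total_km = network.total_length_km()
    rows = []
    for status in sorted(groups):
        dissolved = dissolve(ExposureSet(reaches=groups[status],
                                         scenario=scenario))
        rows.append(ExposureSummary(
            unit_kind="status", unit_id=status, scenario=scenario,
            exposed_km=total_length(dissolved), total_km=total_km))
    return rows


def summarize_sites(exposure: ExposureSet, network: RiverNetwork,
                    cpa: CPALayer, mode: str = "planar"
                    ) -> list[ExposureSummary]:
    """Per-site exposed/total river length (against pre-union polygons)."""
    dissolved = exposure if exposure.dissolved else dissolve(exposure)
    exposed_lines = [interval_geometry(network, r.interval)
                     for r in dissolved.reaches]
    network_lines = [network[s].geometry for s in network.segments]
    exposed_overlay = overlay_lengths(exposed_lines, cpa, mode=mode,
                                      per_site=True)
    total_overlay = overlay_lengths(network_lines, cpa, mode=mode,
                                    per_site=True)
    return [ExposureSummary(
        unit_kind="site", unit_id=site.site_id, scenario=exposure.scenario,
        exposed_km=exposed_overlay.per_site_inside_km[site.site_id],
        total_km=total_overlay.per_site_inside_km[site.site_id])
        for site in cpa.sites]


def summarize_cpa(exposure: ExposureSet, network: RiverNetwork,
                  cpa: CPALayer, mode: str = "planar") -> ExposureSummary:
    """Exposed vs. total river length within the CPA union."""
    dissolved = exposure if exposure.dissolved else dissolve(exposure)
    exposed = _exposed_in_cpa(dissolved.reaches, network, cpa, mode)
    total = overlay_lengths((network[s].geometry for s in network.segments),
                            cpa, mode=mode).inside_km
    return ExposureSummary(unit_kind="cpa", unit_id=cpa.variant,
                           scenario=exposure.scenario,
                           exposed_km=exposed, total_km=total)


def clean_energy_share(per_mine_etm_reaches: Iterable[ExposedReach],
                       demand_table: DemandShareTable,
                       scenario: Scenario) -> tuple[float, float]:
    """(weighted km, unweighted km) of ETM exposure for clean energy.

    Expects per-mine reaches from key-ETM mines only.  The weighted
    length scales each mine's (within-mine unioned) exposure by the mean
    clean-energy demand share of its ETM commodities; the unweighted
    value is the dissolved ETM total.
    """
    reaches = [r for r in per_mine_etm_reaches if is_key_etm(r.commodities)]
    weights: dict[str, float] = {}
    for reach in reaches:
        (mine_id,) = reach.sources
        weights.setdefault(mine_id, demand_share(reach.commodities,
                                                 demand_table))
    weighted = total_length(reaches, weights=weights)
    unweighted = total_length(dissolve(ExposureSet(reaches=reaches,
                                                   scenario=scenario)))
    return weighted, unweighted


def summaries_to_frame(rows: Iterable[ExposureSummary]) -> pd.DataFrame:
    """Tabulate summaries (one row per unit/scenario) for CSV export."""
    records = []
    for r in rows:
        records.append({
            "unit_kind": r.unit_kind,
            "unit_id": r.unit_id,
            "scenario": str(r.scenario.value),
            "exposed_km": r.exposed_km,
            "total_km": r.total_km,
            "proportion": r.proportion,
            "clean_energy_km": r.clean_energy_km,
        })
    return pd.DataFrame.from_records(records)
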