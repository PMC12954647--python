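"""Conservation priority areas (CPA) and river-length overlay.

The CPA layer is the combined extent of Protected Areas (PAs) and Key
Biodiversity Areas (KBAs).  Sites reported only as points are modelled
as circles matching their reported area (marine point sites are
excluded, as buffering marine extents risks spurious terrestrial
overlap).  A stricter variant keeps only nationally designated PAs with
an assigned IUCN management category (I-VI) that are not merely
proposed, plus supplementary national sites retained as provided; KBAs
are excluded from that variant.

Lines exactly on a CPA boundary count as inside (closed polygons).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from shapely.geometry import (LineString, MultiPolygon, Point, Polygon)
from shapely.ops import unary_union
from shapely.validation import make_valid

from .geodesy import geodesic_circle, planar_circle, polyline_length_km

log = logging.getLogger(__name__)

IUCN_CATEGORIES = ("I", "Ia", "Ib", "II", "III", "IV", "V", "VI")

COMBINED_CPA = "combined_cpa"
IUCN_CATEGORIZED_PA = "iucn_categorized_pa"


@dataclass
class ConservationSite:
    """A PA or KBA, as a polygon or as a point with a reported area."""

    site_id: str
    layer: str  # "PA" | "KBA"
    geometry: Polygon | MultiPolygon | Point
    reported_area_km2: float = 0.0
    designation_type: str = "national"  # national | international | supplementary
    iucn_category: Optional[str] = None
    status_flag: str = "designated"
    marine: bool = False

    def __post_init__(self) -> None:
        if self.layer not in ("PA", "KBA"):
            raise ValueError(f"layer must be PA or KBA, got {self.layer!r}")
        if self.reported_area_km2 < 0:
            raise ValueError("reported area must be >= 0")

    @property
    def is_point(self) -> bool:
        return isinstance(self.geometry, Point)


@dataclass
class CPALayer:
    """Union geometry of the included sites under one variant."""

    geometry: Polygon | MultiPolygon
    site_ids: list[str]
    variant: str
    sites: list[ConservationSite] = field(default_factory=list)


def buffer_point_sites(sites: Iterable[ConservationSite],
                       mode: str = "planar") -> list[ConservationSite]:
    """Replace point sites with circles matching their reported area.

    Marine point sites are excluded; points without a reported area are
    dropped with a warning.  Polygon sites pass through unchanged.
    """
    out: list[ConservationSite] = []
    for site in sites:
        if not site.is_point:
            out.append(site)
            continue
        if site.marine:
            log.info("marine point site %s excluded from buffering",
                     site.site_id)
            continue
        if site.reported_area_km2 <= 0:
            log.warning("point site %s has no reported area; dropped",
                        site.site_id)
            continue
        radius = math.sqrt(site.reported_area_km2 / math.pi)
        if mode == "planar":
            circle = planar_circle(site.geometry.x, site.geometry.y, radius)
        else:
            circle = geodesic_circle(site.geometry.x, site.geometry.y, radius)
        buffered = ConservationSite(
            site_id=site.site_id, layer=site.layer, geometry=circle,
            reported_area_km2=site.reported_area_km2,
            designation_type=site.designation_type,
            iucn_category=site.iucn_category, status_flag=site.status_flag,
            marine=site.marine)
        out.append(buffered)
    return out


def passes_iucn_filter(site: ConservationSite) -> bool:
    """Strict-PA inclusion rule (Venter-style).

    Nationally designated PAs with an assigned IUCN category I-VI and
    not classified as proposed; supplementary national-source sites are
    retained as provided (their IUCN metadata is unavailable).
    """
    if site.layer != "PA":
        return False
    if site.designation_type == "supplementary":
        return True
    return (site.designation_type == "national"
            and site.iucn_category in IUCN_CATEGORIES
            and site.status_flag != "proposed")


def build_cpa(pa_sites: Sequence[ConservationSite],
              kba_sites: Sequence[ConservationSite],
              variant: str = COMBINED_CPA) -> CPALayer:
    """Union the included sites into a single CPA geometry.

    Point sites must already be buffered.  Geometries are validity-
    repaired before the union.
    """
    if variant == COMBINED_CPA:
        included = [s for s in list(pa_sites) + list(kba_sites)
                    if not s.is_point]
    elif variant == IUCN_CATEGORIZED_PA:
        included = [s for s in pa_sites
                    if not s.is_point and passes_iucn_filter(s)]
    else:
        raise ValueError(f"unknown CPA variant {variant!r}")
    geoms = [make_valid(s.geometry) for s in included]
    union = unary_union(geoms) if geoms else Polygon()
    return CPALayer(geometry=union, site_ids=[s.site_id for s in included],
                    variant=variant, sites=included)


def _length_km(geom, mode: str) -> float:
    if geom.is_empty:
        return 0.0
    if isinstance(geom, LineString):
        return polyline_length_km(geom.coords, mode)
    if hasattr(geom, "geoms"):
        return sum(_length_km(g, mode) for g in geom.geoms
                   if g.geom_type in ("LineString", "MultiLineString",
                                      "GeometryCollection"))
    return 0.0


@dataclass
class OverlayResult:
    inside_km: float
    outside_km: float
    per_site_inside_km: dict[str, float] = field(default_factory=dict)

    @property
    def total_km(self) -> float:
        return self.inside_km + self.outside_km


def overlay_lengths(lines: Iterable[LineString], cpa: CPALayer,
                    mode: str = "planar",
                    per_site: bool = False) -> OverlayResult:
    """Split line length into inside/outside the CPA union.

    ``inside + outside`` equals the total line length.  Per-site lengths
    are computed against the individual (pre-union) site polygons, so a
    reach inside an overlapping PA and KBA counts once for the union but
    once per each site.
    """
    inside = 0.0
    total = 0.0
    per_site_len: dict[str, float] = {s.site_id: 0.0 for s in cpa.sites} \
        if per_site else {}
    union_empty = cpa.geometry.is_empty
    for line in lines:
        line_len = _length_km(line, mode)
        total += line_len
        if not union_empty and line.intersects(cpa.geometry):
            inside += _length_km(line.intersection(cpa.geometry), mode)
        if per_site:
            for site in cpa.sites:
                if line.intersects(site.geometry):
                    per_site_len[site.site_id] += _length_km(
                        line.intersection(site.geometry), mode)
    return OverlayResult(inside_km=inside, outside_km=total - inside,
                         per_site_inside_km=per_site_len)
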