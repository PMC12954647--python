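"""Ellipsoidal (WGS84) and planar distance measurement.

Two coordinate modes run through the whole package:

``"planar"``
    Coordinates are already in kilometres on a flat plane; lengths are
    Euclidean.  Used for synthetic test worlds where exact arithmetic
    matters.

``"geodesic"``
    Coordinates are longitude/latitude degrees on the WGS84 ellipsoid;
    lengths are geodesic distances computed with Vincenty's formulae.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

from shapely.geometry import Point, Polygon

# WGS84 ellipsoid
_A = 6378137.0                  # semi-major axis, m
_F = 1.0 / 298.257223563        # flattening
_B = _A * (1.0 - _F)            # semi-minor axis, m

MODES = ("planar", "geodesic")


class GeometryError(ValueError):
    """Degenerate or invalid geometry passed to a measurement routine."""


def geodesic_inverse_m(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Geodesic distance in metres between two lon/lat points (Vincenty).

    Accurate to sub-millimetre for non-antipodal pairs; falls back to a
    spherical great-circle estimate if the iteration fails to converge
    (only possible for nearly antipodal points, which never occur for
    river polyline vertices).
    """
    if lon1 == lon2 and lat1 == lat2:
        return 0.0
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1.0 - _F) * math.tan(phi1))
    U2 = math.atan((1.0 - _F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for _ in range(200):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cosU2 * sin_lam,
                               cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0.0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha * sin_alpha
        if cos2_alpha == 0.0:       # equatorial line
            cos_2sigma_m = 0.0
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
        C = _F / 16.0 * cos2_alpha * (4.0 + _F * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * _F * sin_alpha * (
            sigma + C * sin_sigma * (
                cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)))
        if abs(lam - lam_prev) < 1e-12:
            break
    else:  # pragma: no cover - antipodal fallback
        return 6371008.8 * math.acos(
            max(-1.0, min(1.0, sinU1 * sinU2 + cosU1 * cosU2 * math.cos(L))))

    u2 = cos2_alpha * (_A * _A - _B * _B) / (_B * _B)
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    Bc = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    delta_sigma = Bc * sin_sigma * (
        cos_2sigma_m + Bc / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)
            - Bc / 6.0 * cos_2sigma_m * (-3.0 + 4.0 * sin_sigma ** 2)
            * (-3.0 + 4.0 * cos_2sigma_m ** 2)))
    return _B * A * (sigma - delta_sigma)


def geodesic_direct(lon1: float, lat1: float, azimuth_deg: float,
                    distance_m: float) -> tuple[float, float]:
    """Destination lon/lat from a start point, initial bearing and distance."""
    alpha1 = math.radians(azimuth_deg)
    phi1 = math.radians(lat1)
    U1 = math.atan((1.0 - _F) * math.tan(phi1))
    sigma1 = math.atan2(math.tan(U1), math.cos(alpha1))
    sin_alpha = math.cos(U1) * math.sin(alpha1)
    cos2_alpha = 1.0 - sin_alpha * sin_alpha
    u2 = cos2_alpha * (_A * _A - _B * _B) / (_B * _B)
    A = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    Bc = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))

    sigma = distance_m / (_B * A)
    for _ in range(200):
        cos_2sigma_m = math.cos(2.0 * sigma1 + sigma)
        sin_sigma, cos_sigma = math.sin(sigma), math.cos(sigma)
        delta_sigma = Bc * sin_sigma * (
            cos_2sigma_m + Bc / 4.0 * (
                cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)
                - Bc / 6.0 * cos_2sigma_m * (-3.0 + 4.0 * sin_sigma ** 2)
                * (-3.0 + 4.0 * cos_2sigma_m ** 2)))
        sigma_prev = sigma
        sigma = distance_m / (_B * A) + delta_sigma
        if abs(sigma - sigma_prev) < 1e-12:
            break

    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sin_sigma, cos_sigma = math.sin(sigma), math.cos(sigma)
    cos_alpha1 = math.cos(alpha1)
    phi2 = math.atan2(
        sinU1 * cos_sigma + cosU1 * sin_sigma * cos_alpha1,
        (1.0 - _F) * math.hypot(sin_alpha,
                                sinU1 * sin_sigma - cosU1 * cos_sigma * cos_alpha1))
    lam = math.atan2(sin_sigma * math.sin(alpha1),
                     cosU1 * cos_sigma - sinU1 * sin_sigma * cos_alpha1)
    C = _F / 16.0 * cos2_alpha * (4.0 + _F * (4.0 - 3.0 * cos2_alpha))
    cos_2sigma_m = math.cos(2.0 * sigma1 + sigma)
    L = lam - (1.0 - C) * _F * sin_alpha * (
        sigma + C * sin_sigma * (
            cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)))
    return lon1 + math.degrees(L), math.degrees(phi2)


def point_distance_km(p: Sequence[float], q: Sequence[float],
                      mode: str = "planar") -> float:
    """Straight-line distance between two points, km, in the given mode."""
    if mode == "planar":
        return math.hypot(q[0] - p[0], q[1] - p[1])
    return geodesic_inverse_m(p[0], p[1], q[0], q[1]) / 1000.0


def polyline_length_km(coords: Iterable[Sequence[float]],
                       mode: str = "planar") -> float:
    """Length of a vertex sequence, km.

    Raises :class:`GeometryError` for fewer than two vertices.
    """
    pts = list(coords)
    if len(pts) < 2:
        raise GeometryError("polyline needs at least 2 vertices")
    total = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        total += point_distance_km(a, b, mode)
    return total


def geodesic_circle(lon: float, lat: float, radius_km: float,
                    n_vertices: int = 96) -> Polygon:
    """Polygon approximating a geodesic circle of given radius.

    Vertices are placed with the direct geodesic problem at evenly spaced
    azimuths (equivalent to buffering in an azimuthal-equidistant
    projection centred on the point).
    """
    if radius_km <= 0:
        raise GeometryError("circle radius must be positive")
    ring = [geodesic_direct(lon, lat, 360.0 * i / n_vertices, radius_km * 1000.0)
            for i in range(n_vertices)]
    return Polygon(ring)


def planar_circle(x: float, y: float, radius_km: float,
                  quad_segs: int = 64) -> Polygon:
    if radius_km <= 0:
        raise GeometryError("circle radius must be positive")
    return Point(x, y).buffer(radius_km, quad_segs=quad_segs)
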