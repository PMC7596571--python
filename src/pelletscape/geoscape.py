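"""Procurement-landscape geometry and geometry-derived covariates.

A *procurement landscape* is the circular area around a wood-using facility
from which it economically sources fiber.  Radii follow sector and capacity:
pellet mills get 80 km when nominal annual capacity is at least 100 thousand
tons and 48 km otherwise; wood-using power plants get 80 km; pulp mills get
121 km.  This module constructs those circles and every covariate that is a
pure function of the geometry: competing-industry overlap fractions, port
proximity, drought exposure, and resident population.

Distances are haversine great-circle distances on a sphere of mean radius
6371.0088 km.  Circle-circle intersection ("lens") areas are computed in a
local planar approximation at the great-circle centre separation, which is
accurate to well under 0.1% at the <= 322 km separations that can ever
produce a nonzero lens here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union
from shapely import transform as shp_transform

EARTH_RADIUS_KM = 6371.0088

#: procurement radii (km) by sector; pellet radius depends on capacity
PELLET_LARGE_RADIUS_KM = 80.0
PELLET_SMALL_RADIUS_KM = 48.0
POWER_RADIUS_KM = 80.0
PULP_RADIUS_KM = 121.0
LARGE_CAPACITY_TPY = 100_000.0

PORT_THRESHOLD_KM = 121.0
DROUGHT_COVER_THRESHOLD = 0.10
#: drought severity labels that qualify as "extreme drought" exposure
QUALIFYING_SEVERITIES = frozenset({"severe", "extreme", "exceptional"})

SECTORS = ("pellet", "power", "pulp")


@dataclass(frozen=True)
class Facility:
    """A wood-using mill/plant; the unit that defines a landscape."""

    id: str
    lon: float
    lat: float
    capacity_tpy: float
    start_year: Optional[int] = None
    end_year: Optional[int] = None
    sector: str = "pellet"
    region: str = "rest_east"
    ecoregion: str = ""

    def __post_init__(self) -> None:
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError(f"facility {self.id}: coordinates out of range")
        if self.capacity_tpy <= 0:
            raise ValueError(f"facility {self.id}: capacity must be positive")
        if (
            self.start_year is not None
            and self.end_year is not None
            and self.start_year > self.end_year
        ):
            raise ValueError(f"facility {self.id}: start_year > end_year")


@dataclass(frozen=True)
class Landscape:
    """Circular procurement area around a facility centroid."""

    facility_id: str
    lon: float
    lat: float
    radius_km: float

    @property
    def circle_area_km2(self) -> float:
        return math.pi * self.radius_km**2


@dataclass(frozen=True)
class DroughtEvent:
    """Drought footprint recorded for the August preceding a panel year."""

    august_year: int
    severity: str
    footprint: Polygon  # lon/lat polygon

    def __post_init__(self) -> None:
        if self.footprint.is_empty:
            raise ValueError("drought footprint must be non-empty")


def assign_procurement_radius(capacity_tpy: float, sector: str) -> float:
    """Procurement radius in km for a facility of given capacity and sector.

    The 100 thousand tons/year capacity threshold is inclusive ("at least").
    """
    if capacity_tpy <= 0:
        raise ValueError(f"capacity must be positive, got {capacity_tpy}")
    if sector == "pellet":
        return (
            PELLET_LARGE_RADIUS_KM
            if capacity_tpy >= LARGE_CAPACITY_TPY
            else PELLET_SMALL_RADIUS_KM
        )
    if sector == "power":
        return POWER_RADIUS_KM
    if sector == "pulp":
        return PULP_RADIUS_KM
    raise ValueError(f"unknown sector {sector!r}; expected one of {SECTORS}")


def _check_coords(lon: float, lat: float) -> None:
    if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
        raise ValueError(f"coordinates out of range: ({lon}, {lat})")


def great_circle_distance(p1: Sequence[float], p2: Sequence[float]) -> float:
    """Haversine distance in km between two (lon, lat) points."""
    lon1, lat1 = p1
    lon2, lat2 = p2
    _check_coords(lon1, lat1)
    _check_coords(lon2, lat2)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    a = min(1.0, a)
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def haversine_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Dense pairwise haversine distance matrix (km) for point arrays."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lon) > 180.0) or np.any(np.abs(lat) > 90.0):
        raise ValueError("coordinates out of range")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2.0) ** 2
    np.clip(a, 0.0, 1.0, out=a)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def haversine_to_point(
    lon: np.ndarray, lat: np.ndarray, lon0: float, lat0: float
) -> np.ndarray:
    """Haversine distances (km) from many points to one reference point."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    phi = np.radians(lat)
    phi0 = math.radians(lat0)
    dphi = phi - phi0
    dlam = np.radians(lon - lon0)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi) * math.cos(phi0) * np.sin(dlam / 2.0) ** 2
    np.clip(a, 0.0, 1.0, out=a)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def circle_lens_area(r1: float, r2: float, d: float) -> float:
    """Planar intersection area of two circles with radii r1, r2 and
    centre separation d (all km).  Zero when disjoint; the smaller circle's
    area when nested."""
    if r1 <= 0 or r2 <= 0:
        raise ValueError("radii must be positive")
    if d < 0:
        raise ValueError("separation must be non-negative")
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return math.pi * min(r1, r2) ** 2
    # standard two-circle lens
    d1 = (d**2 + r1**2 - r2**2) / (2.0 * d)
    d2 = d - d1
    a1 = r1**2 * math.acos(max(-1.0, min(1.0, d1 / r1)))
    a2 = r2**2 * math.acos(max(-1.0, min(1.0, d2 / r2)))
    t1 = d1 * math.sqrt(max(0.0, r1**2 - d1**2))
    t2 = d2 * math.sqrt(max(0.0, r2**2 - d2**2))
    return a1 - t1 + a2 - t2


def circle_intersection_area(c1: Landscape, c2: Landscape) -> float:
    """Lens area (km²) between two procurement landscapes, with centre
    separation measured along the great circle."""
    d = great_circle_distance((c1.lon, c1.lat), (c2.lon, c2.lat))
    return circle_lens_area(c1.radius_km, c2.radius_km, d)


def overlap_fraction(target: Landscape, others: Iterable[Landscape]) -> float:
    """Summed lens areas of ``others`` against ``target``, divided by the
    target circle area.  May exceed 1 when the area is overlapped more than
    once.  Callers must exclude the target itself (self-overlap) and
    facilities not operational in the period of interest."""
    area = target.circle_area_km2
    if area <= 0:
        raise ValueError(f"landscape {target.facility_id}: zero-area target")
    total = 0.0
    for other in others:
        total += circle_intersection_area(target, other)
    return total / area


def proximity_flag(
    centroid: Sequence[float],
    ports: Sequence[Sequence[float]],
    threshold_km: float = PORT_THRESHOLD_KM,
) -> int:
    """1 iff the nearest port lies strictly within ``threshold_km``."""
    best = math.inf
    for p in ports:
        best = min(best, great_circle_distance(centroid, (p[0], p[1])))
    return int(best < threshold_km)


# -- local planar projection (for polygon work: drought footprints, output
#    circle polygons).  Equirectangular about an anchor point: exact enough
#    for footprints a few hundred km across.

def local_km_transform(anchor_lon: float, anchor_lat: float):
    """Return (to_km, to_lonlat) coordinate-array transforms about an anchor."""
    kx = EARTH_RADIUS_KM * math.cos(math.radians(anchor_lat)) * math.pi / 180.0
    ky = EARTH_RADIUS_KM * math.pi / 180.0

    def to_km(coords: np.ndarray) -> np.ndarray:
        out = np.empty_like(coords, dtype=float)
        out[:, 0] = (coords[:, 0] - anchor_lon) * kx
        out[:, 1] = (coords[:, 1] - anchor_lat) * ky
        return out

    def to_lonlat(coords: np.ndarray) -> np.ndarray:
        out = np.empty_like(coords, dtype=float)
        out[:, 0] = coords[:, 0] / kx + anchor_lon
        out[:, 1] = coords[:, 1] / ky + anchor_lat
        return out

    return to_km, to_lonlat


def landscape_polygon(landscape: Landscape, n_segments: int = 64) -> Polygon:
    """Circle polygon (lon/lat, ``n_segments`` vertices) for GeoJSON output."""
    _, to_lonlat = local_km_transform(landscape.lon, landscape.lat)
    circle = Point(0.0, 0.0).buffer(landscape.radius_km, quad_segs=n_segments // 4)
    return shp_transform(circle, to_lonlat)


def drought_covered_fraction(
    landscape: Landscape, events: Iterable[DroughtEvent], panel_year: int
) -> float:
    """Fraction of the landscape circle covered by qualifying drought
    footprints recorded in the August preceding ``panel_year``."""
    to_km, _ = local_km_transform(landscape.lon, landscape.lat)
    circle = Point(0.0, 0.0).buffer(landscape.radius_km, quad_segs=64)
    relevant = [
        shp_transform(ev.footprint, to_km)
        for ev in events
        if ev.august_year == panel_year - 1 and ev.severity in QUALIFYING_SEVERITIES
    ]
    if not relevant:
        return 0.0
    covered = circle.intersection(unary_union(relevant))
    return covered.area / circle.area


def drought_flag(
    landscape: Landscape, events: Iterable[DroughtEvent], panel_year: int
) -> int:
    """1 iff at least 10% of the procurement circle was under severe,
    extreme or exceptional drought in the August preceding ``panel_year``."""
    return int(drought_covered_fraction(landscape, events, panel_year) >= DROUGHT_COVER_THRESHOLD)


def population_in_landscape(
    landscape: Landscape,
    unit_lonlat: np.ndarray,
    unit_counts: np.ndarray,
) -> float:
    """Population (thousands) of units whose representative point falls
    strictly inside the landscape circle."""
    unit_lonlat = np.asarray(unit_lonlat, dtype=float)
    unit_counts = np.asarray(unit_counts, dtype=float)
    if np.any(unit_counts < 0):
        raise ValueError("population counts must be non-negative")
    if unit_lonlat.size == 0:
        return 0.0
    d = haversine_to_point(
        unit_lonlat[:, 0], unit_lonlat[:, 1], landscape.lon, landscape.lat
    )
    inside = d < landscape.radius_km
    return float(unit_counts[inside].sum()) / 1000.0


def operational_in_window(
    start_year: Optional[int], end_year: Optional[int], panel_year: int, window_years: int = 3
) -> bool:
    """True iff [start, end] intersects the sampling window
    [panel_year - window + 1, panel_year].  An open end means still running."""
    if start_year is None:
        return False
    lo = panel_year - (window_years - 1)
    e = end_year if end_year is not None else 10**9
    return start_year <= panel_year and e >= lo


def build_landscape(facility: Facility) -> Landscape:
    return Landscape(
        facility_id=facility.id,
        lon=facility.lon,
        lat=facility.lat,
        radius_km=assign_procurement_radius(facility.capacity_tpy, facility.sector),
    )
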