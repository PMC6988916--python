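"""Coordinate handling: UTM (transverse Mercator) projection and great-circle distances.

Within-country samples are analysed in the UTM zone of the country (planar
metres); pooled pantropical samples keep geographic coordinates and use
great-circle distances, since no single projected system spans three
continents.

The forward/inverse transverse Mercator uses the Krüger series in the third
flattening n, accurate to well below a millimetre for the zone widths used
here (WGS84 ellipsoid, scale 0.9996, false easting 500 km, false northing
10,000 km on the southern hemisphere).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
UTM_K0 = 0.9996
UTM_FALSE_EASTING = 500_000.0
UTM_FALSE_NORTHING_SOUTH = 10_000_000.0

#: IUGG mean Earth radius [m], used for great-circle distances.
EARTH_RADIUS = 6_371_008.8

#: UTM zone the source material assigns to each country.
COUNTRY_UTM_ZONE = {"ZAM": "35S", "ECU": "17S", "PHI": "51N"}

_ZONE_RE = re.compile(r"^(\d{1,2})([NS])$")


@dataclass(frozen=True)
class UtmZone:
    number: int
    south: bool

    @property
    def central_meridian(self) -> float:
        return -183.0 + 6.0 * self.number

    @property
    def false_northing(self) -> float:
        return UTM_FALSE_NORTHING_SOUTH if self.south else 0.0


def parse_zone(spec: str) -> UtmZone:
    """Parse a zone spec like ``"35S"`` or ``"51N"``."""
    m = _ZONE_RE.match(spec.strip().upper())
    if m is None:
        raise ValueError(f"not a UTM zone spec: {spec!r}")
    number = int(m.group(1))
    if not 1 <= number <= 60:
        raise ValueError(f"UTM zone number out of range: {number}")
    return UtmZone(number, m.group(2) == "S")


def zone_for_country(country: str) -> UtmZone:
    try:
        return parse_zone(COUNTRY_UTM_ZONE[country])
    except KeyError:
        raise ValueError(f"no default UTM zone for country {country!r}") from None


def _kruger_constants():
    n = WGS84_F / (2.0 - WGS84_F)
    n2, n3, n4, n5, n6 = n**2, n**3, n**4, n**5, n**6
    radius = WGS84_A / (1 + n) * (1 + n2 / 4 + n4 / 64 + n6 / 256)
    alpha = np.array([
        n / 2 - 2 * n2 / 3 + 5 * n3 / 16 + 41 * n4 / 180 - 127 * n5 / 288
        + 7891 * n6 / 37800,
        13 * n2 / 48 - 3 * n3 / 5 + 557 * n4 / 1440 + 281 * n5 / 630
        - 1983433 * n6 / 1935360,
        61 * n3 / 240 - 103 * n4 / 140 + 15061 * n5 / 26880
        + 167603 * n6 / 181440,
        49561 * n4 / 161280 - 179 * n5 / 168 + 6601661 * n6 / 7257600,
        34729 * n5 / 80640 - 3418889 * n6 / 1995840,
        212378941 * n6 / 319334400,
    ])
    beta = np.array([
        n / 2 - 2 * n2 / 3 + 37 * n3 / 96 - n4 / 360 - 81 * n5 / 512
        + 96199 * n6 / 604800,
        n2 / 48 + n3 / 15 - 437 * n4 / 1440 + 46 * n5 / 105
        - 1118711 * n6 / 3870720,
        17 * n3 / 480 - 37 * n4 / 840 - 209 * n5 / 4480 + 5569 * n6 / 90720,
        4397 * n4 / 161280 - 11 * n5 / 504 - 830251 * n6 / 7257600,
        4583 * n5 / 161280 - 108847 * n6 / 3991680,
        20648693 * n6 / 638668800,
    ])
    return n, radius, alpha, beta


_N, _RADIUS, _ALPHA, _BETA = _kruger_constants()
_E = math.sqrt(WGS84_F * (2.0 - WGS84_F))  # first eccentricity


def geographic_to_utm(lon, lat, zone: UtmZone):
    """Project geographic WGS84 coordinates [deg] to UTM easting/northing [m].

    Accepts scalars or arrays; returns (easting, northing) of the same shape.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lam = np.radians(lon - zone.central_meridian)
    phi = np.radians(lat)

    two_sqrt_n = 2.0 * math.sqrt(_N) / (1.0 + _N)
    t = np.sinh(np.arctanh(np.sin(phi))
                - two_sqrt_n * np.arctanh(two_sqrt_n * np.sin(phi)))
    xi = np.arctan2(t, np.cos(lam))
    eta = np.arcsinh(np.sin(lam) / np.hypot(t, np.cos(lam)))

    j = np.arange(1, 7)
    xi_full = xi + np.sum(
        _ALPHA * np.sin(2 * np.multiply.outer(xi, j))
        * np.cosh(2 * np.multiply.outer(eta, j)), axis=-1)
    eta_full = eta + np.sum(
        _ALPHA * np.cos(2 * np.multiply.outer(xi, j))
        * np.sinh(2 * np.multiply.outer(eta, j)), axis=-1)

    easting = UTM_FALSE_EASTING + UTM_K0 * _RADIUS * eta_full
    northing = zone.false_northing + UTM_K0 * _RADIUS * xi_full
    return easting, northing


def utm_to_geographic(easting, northing, zone: UtmZone):
    """Inverse of :func:`geographic_to_utm`; returns (lon, lat) in degrees."""
    easting = np.asarray(easting, dtype=float)
    northing = np.asarray(northing, dtype=float)
    xi = (northing - zone.false_northing) / (UTM_K0 * _RADIUS)
    eta = (easting - UTM_FALSE_EASTING) / (UTM_K0 * _RADIUS)

    j = np.arange(1, 7)
    xi_p = xi - np.sum(
        _BETA * np.sin(2 * np.multiply.outer(xi, j))
        * np.cosh(2 * np.multiply.outer(eta, j)), axis=-1)
    eta_p = eta - np.sum(
        _BETA * np.cos(2 * np.multiply.outer(xi, j))
        * np.sinh(2 * np.multiply.outer(eta, j)), axis=-1)

    lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))
    tau_p = np.sin(xi_p) / np.hypot(np.sinh(eta_p), np.cos(xi_p))

    # invert the conformal latitude by Newton iteration on phi
    phi = np.arctan(tau_p)
    for _ in range(8):
        s = np.sin(phi)
        f = (np.sinh(np.arcsinh(np.tan(phi)) - _E * np.arctanh(_E * s))
             - tau_p)
        inner = np.cosh(np.arcsinh(np.tan(phi)) - _E * np.arctanh(_E * s))
        df = inner * (1.0 / np.cos(phi) - _E**2 * np.cos(phi) / (1 - _E**2 * s**2))
        phi = phi - f / df
    lon = np.degrees(lam) + zone.central_meridian
    lat = np.degrees(phi)
    return lon, lat


def great_circle_distance(lon1, lat1, lon2, lat2, radius: float = EARTH_RADIUS):
    """Great-circle (haversine) distance [m] between geographic points [deg]."""
    lon1, lat1 = np.radians(lon1), np.radians(lat1)
    lon2, lat2 = np.radians(lon2), np.radians(lat2)
    dphi = lat2 - lat1
    dlam = lon2 - lon1
    h = np.sin(dphi / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlam / 2) ** 2
    return 2.0 * radius * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def great_circle_matrix(lonlat: np.ndarray, radius: float = EARTH_RADIUS) -> np.ndarray:
    """Pairwise great-circle distance matrix [m] for an (n, 2) lon/lat array."""
    lonlat = np.asarray(lonlat, dtype=float)
    lon = np.radians(lonlat[:, 0])
    lat = np.radians(lonlat[:, 1])
    h = (np.sin((lat[:, None] - lat[None, :]) / 2) ** 2
         + np.outer(np.cos(lat), np.cos(lat))
         * np.sin((lon[:, None] - lon[None, :]) / 2) ** 2)
    return 2.0 * radius * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
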