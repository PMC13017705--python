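"""Small shared helpers: rounding, angles, spherical geometry."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

#: Mean Earth radius (IUGG), km.
EARTH_RADIUS_KM = 6371.0088


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention used in reports).

    Python's built-in ``round`` uses banker's rounding, which would turn
    94.45 into 94.4; reported percentages use half-up instead.
    """
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def wrap_lon(lon):
    """Wrap longitudes to [-180, 180)."""
    return (np.asarray(lon) + 180.0) % 360.0 - 180.0


def wrap_dlon(dlon: float) -> float:
    """Wrap a longitude difference to the interval (-180, 180]."""
    d = (dlon + 180.0) % 360.0 - 180.0
    if d == -180.0:
        d = 180.0
    return d


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km on a sphere of radius EARTH_RADIUS_KM."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def lonlat_to_unit_vectors(lon, lat):
    """Convert degree coordinates to 3-D unit vectors, shape (n, 3)."""
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    return np.stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)], axis=-1
    )


def unit_vector_to_lonlat(v) -> tuple[float, float]:
    """Convert one 3-D vector (not necessarily normalized) to (lon, lat) degrees."""
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero-length vector has no direction")
    x, y, z = v / norm
    lat = float(np.degrees(np.arcsin(np.clip(z, -1.0, 1.0))))
    lon = float(np.degrees(np.arctan2(y, x)))
    if lon == 180.0:
        lon = -180.0
    return lon, lat


def circular_mean_deg(angles) -> float:
    """Vector mean of angles in degrees, result in (-180, 180]."""
    a = np.radians(np.asarray(angles, dtype=float))
    s, c = np.sin(a).mean(), np.cos(a).mean()
    out = float(np.degrees(np.arctan2(s, c)))
    return wrap_dlon(out)
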