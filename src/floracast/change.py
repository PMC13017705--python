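"""Per-species change metrics: AOH deltas, stability classes, centroid migration.

A species is *stable* when its relative AOH change is within the stability
band (default +/-5% of the current AOH), *extinct* when its future AOH is
zero. Centroids are area-weighted spherical means of occupied cells, so the
statistics behave across the antimeridian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from ._utils import (
    circular_mean_deg,
    haversine_km,
    lonlat_to_unit_vectors,
    unit_vector_to_lonlat,
    wrap_dlon,
)
from .errors import NoCentroidError, UndefinedBaselineError
from .projection import RangeMap

EXPANSION = "expansion"
CONTRACTION = "contraction"
STABLE = "stable"

NORTHWARD = "northward"
SOUTHWARD = "southward"
STABLE_LATITUDE = "stable-latitude"


def classify_change(aoh_now: float, aoh_future: float, stability_band: float = 0.05) -> str:
    """Classify AOH change with a relative stability band around zero.

    |future - now| / now <= band -> stable, otherwise expansion or contraction
    by the sign of the change. A zero baseline is undefined.
    """
    if aoh_now <= 0:
        raise UndefinedBaselineError("current AOH is zero; change class undefined")
    rel = (aoh_future - aoh_now) / aoh_now
    if abs(rel) <= stability_band:
        return STABLE
    return EXPANSION if rel > 0 else CONTRACTION


def centroid(range_map: RangeMap) -> tuple[float, float]:
    """Area-weighted spherical centroid (lon, lat) of the occupied cells."""
    occ = range_map.occupancy
    if not occ.any():
        raise NoCentroidError(f"{range_map.species_id}: empty occupancy")
    rows, cols = np.nonzero(occ)
    lon = range_map.lon_centers[cols]
    lat = range_map.lat_centers[rows]
    w = range_map.cell_areas()[rows, cols]
    v = lonlat_to_unit_vectors(lon, lat)
    mean_v = (v * w[:, None]).sum(axis=0) / w.sum()
    return unit_vector_to_lonlat(mean_v)


def migration_vector(
    centroid_now: tuple[float, float], centroid_future: tuple[float, float]
) -> tuple[float, float, float, str]:
    """(dlat, dlon, shift_km, direction_class) between two centroids.

    dlon is wrapped to (-180, 180]; shift is the haversine great-circle
    distance; direction is northward iff dlat > 0, southward iff dlat < 0,
    and "stable-latitude" at exactly zero (counted as non-northward).
    """
    lon_n, lat_n = centroid_now
    lon_f, lat_f = centroid_future
    dlat = lat_f - lat_n
    dlon = wrap_dlon(lon_f - lon_n)
    shift = haversine_km(lon_n, lat_n, lon_f, lat_f)
    if dlat > 0:
        direction = NORTHWARD
    elif dlat < 0:
        direction = SOUTHWARD
    else:
        direction = STABLE_LATITUDE
    return dlat, dlon, shift, direction


@dataclass
class ChangeSummary:
    """One species x (period, scenario) row of the change table."""

    species_id: str
    period: str
    scenario: str
    aoh_now_km2: float
    aoh_future_km2: float
    delta_km2: float
    fold_change: float | None  # (future - now) / now; None when now == 0
    change_class: str | None  # None when the baseline AOH is zero
    extinct_flag: bool
    centroid_now: tuple[float, float] | None
    centroid_future: tuple[float, float] | None
    dlat: float | None
    dlon: float | None
    shift_km: float | None
    direction_class: str | None

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_change(
    map_now: RangeMap, map_future: RangeMap, stability_band: float = 0.05
) -> ChangeSummary:
    """Build the full change summary for one species under one future climate.

    Species with an empty future range are flagged extinct (change class
    contraction) and carry no migration vector; species with an empty current
    range have an undefined baseline (class None) and no vector either.
    """
    if map_now.species_id != map_future.species_id:
        raise ValueError("range maps belong to different species")
    aoh_now, aoh_future = map_now.aoh_km2, map_future.aoh_km2
    extinct = aoh_future == 0.0

    fold = change_class = None
    if aoh_now > 0:
        fold = (aoh_future - aoh_now) / aoh_now
        change_class = CONTRACTION if extinct else classify_change(
            aoh_now, aoh_future, stability_band
        )

    c_now = c_future = None
    dlat = dlon = shift = direction = None
    if aoh_now > 0:
        c_now = centroid(map_now)
    if not extinct:
        c_future = centroid(map_future)
    if c_now is not None and c_future is not None:
        dlat, dlon, shift, direction = migration_vector(c_now, c_future)

    return ChangeSummary(
        species_id=map_now.species_id,
        period=map_future.period,
        scenario=map_future.scenario,
        aoh_now_km2=aoh_now,
        aoh_future_km2=aoh_future,
        delta_km2=aoh_future - aoh_now,
        fold_change=fold,
        change_class=change_class,
        extinct_flag=extinct,
        centroid_now=c_now,
        centroid_future=c_future,
        dlat=dlat,
        dlon=dlon,
        shift_km=shift,
        direction_class=direction,
    )


@dataclass
class SectorMigration:
    """Mean migration statistics over the species assigned to one sector."""

    sector_id: str
    n_species: int
    mean_dlat: float
    mean_dlon: float
    mean_shift_km: float
    pct_northward: float
    n_extinct: int


def sector_mean_migration(
    change_summaries: list[ChangeSummary],
    sector_id: str,
    sector_of_centroid,
) -> SectorMigration | None:
    """Unweighted mean migration over species whose current centroid is in a sector.

    ``sector_of_centroid`` maps (lon, lat) to a sector label. Species without
    a defined migration vector (extinct or no baseline) are excluded from the
    means; extinctions are tallied separately. An empty sector returns None
    with a warning.
    """
    members = [
        s
        for s in change_summaries
        if s.centroid_now is not None and sector_of_centroid(*s.centroid_now) == sector_id
    ]
    if not members:
        warnings.warn(f"sector {sector_id!r}: no species assigned; summary undefined")
        return None
    with_vec = [s for s in members if s.dlat is not None]
    n_extinct = sum(s.extinct_flag for s in members)
    if not with_vec:
        warnings.warn(f"sector {sector_id!r}: no defined migration vectors")
        return SectorMigration(
            sector_id, len(members), float("nan"), float("nan"), float("nan"),
            float("nan"), n_extinct,
        )
    dlats = np.array([s.dlat for s in with_vec])
    return SectorMigration(
        sector_id=sector_id,
        n_species=len(members),
        mean_dlat=float(dlats.mean()),
        mean_dlon=circular_mean_deg([s.dlon for s in with_vec]),
        mean_shift_km=float(np.mean([s.shift_km for s in with_vec])),
        pct_northward=float(100.0 * (dlats > 0).sum() / len(with_vec)),
        n_extinct=n_extinct,
    )
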