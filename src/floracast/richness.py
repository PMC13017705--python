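"""Stacked species richness, MSR, richness change, and per-sector roll-ups.

Richness maps are per-cell counts of occupying species; MSR ("mean species
richness", species per grid cell) is the unweighted mean over a cell mask,
matching the per-grid-cell convention (an area-weighted variant is available
behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import round_half_up, wrap_lon
from .change import ChangeSummary, sector_mean_migration, CONTRACTION, EXPANSION, STABLE
from .errors import AlignmentError, InvalidConfigError, UndefinedMSRError
from .projection import RangeMap, grid_cell_areas
from .synthetic import ClimateGrid

NO_SECTOR = "none"

#: Longitude-band stand-ins for the five Arctic sectors; the real boundaries
#: are a user-supplied polygon/band file.
DEFAULT_SECTOR_BANDS = [
    ("ER-WSS", 30.0, 90.0),
    ("ESS", 90.0, 160.0),
    ("BS", 160.0, -140.0),  # crosses the antimeridian
    ("CS", -140.0, -60.0),
    ("NAS", -60.0, 30.0),
]


@dataclass
class SectorMask:
    """Per-cell sector labels over a grid, built from longitude bands."""

    lon_centers: np.ndarray
    lat_centers: np.ndarray
    labels: np.ndarray  # (n_lat, n_lon) array of strings
    sector_ids: list[str]

    @classmethod
    def from_lon_bands(
        cls,
        grid: ClimateGrid,
        bands: list[tuple[str, float, float]] | None = None,
        lat_min: float | None = None,
    ) -> "SectorMask":
        """Label cells by [lon_min, lon_max) bands; bands may wrap at 180.

        Cells south of ``lat_min`` (if given) are labelled "none".
        """
        bands = DEFAULT_SECTOR_BANDS if bands is None else bands
        labels = np.full(grid.shape, NO_SECTOR, dtype=object)
        lon = wrap_lon(grid.lon_centers)
        for name, lo, hi in bands:
            if lo <= hi:
                cols = (lon >= lo) & (lon < hi)
            else:  # wrap across the antimeridian
                cols = (lon >= lo) | (lon < hi)
            labels[:, cols] = name
        if lat_min is not None:
            labels[grid.lat_centers < lat_min, :] = NO_SECTOR
        return cls(
            lon_centers=grid.lon_centers.copy(),
            lat_centers=grid.lat_centers.copy(),
            labels=labels,
            sector_ids=[b[0] for b in bands],
        )

    def sector_of(self, lon: float, lat: float) -> str:
        """Sector label at a point; "none" outside the grid."""
        res = float(self.lat_centers[1] - self.lat_centers[0]) if self.lat_centers.size > 1 else 1.0
        col = int(np.floor((lon - (self.lon_centers[0] - res / 2)) / res))
        row = int(np.floor((lat - (self.lat_centers[0] - res / 2)) / res))
        if 0 <= row < self.labels.shape[0] and 0 <= col < self.labels.shape[1]:
            return str(self.labels[row, col])
        return NO_SECTOR

    def cells(self, sector_id: str) -> np.ndarray:
        return self.labels == sector_id


@dataclass
class RichnessMap:
    """Per-cell species counts for one (period, scenario)."""

    counts: np.ndarray  # (n_lat, n_lon) nonnegative integers
    period: str
    scenario: str
    lon_centers: np.ndarray
    lat_centers: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


def stack_richness(range_maps: list[RangeMap]) -> RichnessMap:
    """Sum binary occupancies into a richness surface.

    All maps must share one grid and one (period, scenario).
    """
    if not range_maps:
        raise InvalidConfigError("stack_richness needs at least one range map")
    first = range_maps[0]
    counts = np.zeros(first.shape, dtype=np.int64)
    for m in range_maps:
        if not first.same_grid(m):
            raise AlignmentError(f"{m.species_id}: grid mismatch")
        if (m.period, m.scenario) != (first.period, first.scenario):
            raise AlignmentError(
                f"{m.species_id}: ({m.period}, {m.scenario}) != "
                f"({first.period}, {first.scenario})"
            )
        counts += m.occupancy.astype(np.int64)
    return RichnessMap(
        counts=counts,
        period=first.period,
        scenario=first.scenario,
        lon_centers=first.lon_centers.copy(),
        lat_centers=first.lat_centers.copy(),
    )


def mean_species_richness(
    richness_map: RichnessMap,
    mask: np.ndarray | None = None,
    area_weighted: bool = False,
) -> float:
    """MSR in species per grid cell over the masked cells, to one decimal."""
    counts = richness_map.counts
    m = np.ones(counts.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    if not m.any():
        raise UndefinedMSRError("mask selects no cells")
    if area_weighted:
        from .projection import cell_area_km2

        res = float(richness_map.lat_centers[1] - richness_map.lat_centers[0])
        w = np.broadcast_to(
            np.atleast_1d(cell_area_km2(richness_map.lat_centers, res))[:, None], counts.shape
        )
        msr = float((counts * w)[m].sum() / w[m].sum())
    else:
        msr = float(counts[m].mean())
    return round_half_up(msr, 1)


def richness_change(
    richness_future: RichnessMap, richness_current: RichnessMap
) -> tuple[np.ndarray, dict]:
    """Per-cell richness difference (future - current) plus a gain/loss summary.

    The summary reports area-weighted fractions of cells gaining, losing and
    unchanged.
    """
    if richness_future.shape != richness_current.shape or not (
        np.allclose(richness_future.lon_centers, richness_current.lon_centers)
        and np.allclose(richness_future.lat_centers, richness_current.lat_centers)
    ):
        raise AlignmentError("richness maps on different grids")
    diff = richness_future.counts - richness_current.counts
    from .projection import cell_area_km2

    lats = richness_current.lat_centers
    res = float(lats[1] - lats[0]) if lats.size > 1 else 1.0
    w = np.broadcast_to(np.atleast_1d(cell_area_km2(lats, res))[:, None], diff.shape)
    total = w.sum()
    summary = {
        "frac_gaining": float(w[diff > 0].sum() / total),
        "frac_losing": float(w[diff < 0].sum() / total),
        "frac_unchanged": float(w[diff == 0].sum() / total),
    }
    return diff, summary


def sector_summary(
    range_maps_now: dict[str, RangeMap],
    change_summaries: list[ChangeSummary],
    richness_maps: dict[tuple[str, str], RichnessMap],
    sector_mask: SectorMask,
) -> pd.DataFrame:
    """Per sector x (period, scenario) report.

    Species are assigned to the sector containing their current centroid.
    Columns: counts of expanding/contracting/stable species, mean fold change,
    extinction count, MSR, and mean migration vector.
    """
    rows = []
    by_ps: dict[tuple[str, str], list[ChangeSummary]] = {}
    for s in change_summaries:
        by_ps.setdefault((s.period, s.scenario), []).append(s)

    for (period, scenario), summaries in sorted(by_ps.items()):
        for sector in sector_mask.sector_ids:
            members = [
                s
                for s in summaries
                if s.centroid_now is not None
                and sector_mask.sector_of(*s.centroid_now) == sector
            ]
            classes = [s.change_class for s in members if s.change_class is not None]
            folds = [s.fold_change for s in members if s.fold_change is not None]
            mig = (
                sector_mean_migration(summaries, sector, sector_mask.sector_of)
                if members
                else None
            )
            rmap = richness_maps.get((period, scenario))
            msr = (
                mean_species_richness(rmap, sector_mask.cells(sector))
                if rmap is not None and sector_mask.cells(sector).any()
                else None
            )
            rows.append(
                {
                    "sector": sector,
                    "period": period,
                    "scenario": scenario,
                    "n_species": len(members),
                    "n_expanding": classes.count(EXPANSION),
                    "n_contracting": classes.count(CONTRACTION),
                    "n_stable": classes.count(STABLE),
                    "n_extinct": sum(s.extinct_flag for s in members),
                    "mean_fold_change": float(np.mean(folds)) if folds else np.nan,
                    "msr_spgc": msr,
                    "mean_dlat": mig.mean_dlat if mig else np.nan,
                    "mean_dlon": mig.mean_dlon if mig else np.nan,
                    "mean_shift_km": mig.mean_shift_km if mig else np.nan,
                    "pct_northward": mig.pct_northward if mig else np.nan,
                }
            )
    return pd.DataFrame(rows)
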