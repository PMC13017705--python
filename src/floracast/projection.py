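"""Project ensembles onto the period x scenario climate matrix and binarize.

One :class:`RangeMap` per (species, period, scenario): continuous suitability,
binary occupancy at the species' max-TSS threshold (fit once on current-period
data, reused for every projection), and area of habitat in km^2 computed with
spherical cell areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._utils import EARTH_RADIUS_KM
from .ensemble import EnsembleModel
from .errors import InvalidLatitudeError, ProjectionError
from .synthetic import ClimateGrid

logger = logging.getLogger(__name__)


def cell_area_km2(lat_center, resolution: float, lon_resolution: float | None = None):
    """Spherical area of a lat/lon cell: R^2 * dlam * (sin(lat2) - sin(lat1)).

    ``resolution`` is the latitudinal cell height in degrees;
    ``lon_resolution`` defaults to the same value. Accepts scalars or arrays.
    """
    lat = np.asarray(lat_center, dtype=float)
    if lon_resolution is None:
        lon_resolution = resolution
    if np.any(np.abs(lat) + resolution / 2.0 > 90.0 + 1e-9):
        raise InvalidLatitudeError("cell extends past a pole")
    phi1 = np.radians(lat - resolution / 2.0)
    phi2 = np.radians(lat + resolution / 2.0)
    dlam = np.radians(lon_resolution)
    area = EARTH_RADIUS_KM**2 * dlam * (np.sin(phi2) - np.sin(phi1))
    return float(area) if np.isscalar(lat_center) else area


def grid_cell_areas(grid: ClimateGrid) -> np.ndarray:
    """Per-cell spherical areas (n_lat, n_lon), constant along each row."""
    res = grid.resolution
    row_areas = cell_area_km2(grid.lat_centers, res)
    return np.broadcast_to(np.atleast_1d(row_areas)[:, None], grid.shape).copy()


@dataclass
class RangeMap:
    """Suitability + binary occupancy for one species under one climate."""

    species_id: str
    period: str
    scenario: str
    lon_centers: np.ndarray
    lat_centers: np.ndarray
    suitability: np.ndarray  # (n_lat, n_lon) in [0, 1]
    occupancy: np.ndarray  # boolean, same shape
    threshold: float
    aoh_km2: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.occupancy.shape

    @property
    def resolution(self) -> float:
        if self.lat_centers.size > 1:
            return float(self.lat_centers[1] - self.lat_centers[0])
        return float(self.lon_centers[1] - self.lon_centers[0])

    def cell_areas(self) -> np.ndarray:
        res = self.resolution
        rows = cell_area_km2(self.lat_centers, res)
        return np.broadcast_to(np.atleast_1d(rows)[:, None], self.shape).copy()

    def same_grid(self, other: "RangeMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lon_centers, other.lon_centers)
            and np.allclose(self.lat_centers, other.lat_centers)
        )


def make_range_map(
    species_id: str,
    grid: ClimateGrid,
    suitability: np.ndarray,
    threshold: float,
) -> RangeMap:
    """Binarize a suitability surface and compute its AOH."""
    occupancy = suitability >= threshold
    aoh = float(grid_cell_areas(grid)[occupancy].sum())
    return RangeMap(
        species_id=species_id,
        period=grid.period,
        scenario=grid.scenario,
        lon_centers=grid.lon_centers,
        lat_centers=grid.lat_centers,
        suitability=suitability,
        occupancy=occupancy,
        threshold=threshold,
        aoh_km2=aoh,
    )


def project_species(
    model: EnsembleModel,
    climate_grids: list[ClimateGrid],
    study_mask: np.ndarray | None = None,
) -> list[RangeMap]:
    """Project one species' ensemble onto every supplied climate grid.

    Covariate values outside the training range are clamped to the training
    min/max (extrapolation fraction logged per grid). The species' single
    max-TSS threshold binarizes every map. ``study_mask`` (True = inside)
    optionally zeroes suitability outside the study extent.
    """
    if model.threshold_tss is None:
        raise ProjectionError(f"{model.species_id}: threshold_tss not set")
    maps = []
    for grid in climate_grids:
        missing = [n for n in model.covariate_names if n not in grid.covariates]
        if missing:
            raise ProjectionError(
                f"{model.species_id}: grid ({grid.period}, {grid.scenario}) "
                f"missing covariate(s) {missing}"
            )
        X = grid.covariate_matrix(model.covariate_names)
        outside = (X < model.train_min) | (X > model.train_max)
        frac = float(outside.any(axis=1).mean())
        if frac > 0:
            logger.info(
                "%s (%s, %s): clamped covariates in %.1f%% of cells",
                model.species_id,
                grid.period,
                grid.scenario,
                100 * frac,
            )
        suit = model.predict(X, clamp=True).reshape(grid.shape)
        if study_mask is not None:
            suit = np.where(np.asarray(study_mask, dtype=bool), suit, 0.0)
        maps.append(make_range_map(model.species_id, grid, suit, model.threshold_tss))
    return maps
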