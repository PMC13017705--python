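"""Virtual-species synthetic data: climate grids, species, biased occurrence samples.

The generators here provide ground truth for every downstream stage: climate
grids for one current period plus a 4-period x 4-scenario future matrix,
virtual species with known Gaussian response surfaces and true ranges, and
presence-only occurrence samples drawn with configurable spatial bias.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import (
    InvalidConfigError,
    InvalidExtentError,
    InvalidParameterError,
    NoHabitatError,
)

#: Canonical future period labels, in chronological order.
PERIODS = ("2030s", "2050s", "2070s", "2090s")
#: Emission scenarios from low to high forcing.
SCENARIOS = ("SSP1-2.6", "SSP2-4.5", "SSP3-7.0", "SSP5-8.5")

CURRENT_PERIOD = "current"
NO_SCENARIO = "none"

#: Default warming increments (degrees C) per period and scenario; nondecreasing
#: along both axes.
DEFAULT_WARMING = {
    "2030s": {"SSP1-2.6": 0.6, "SSP2-4.5": 0.7, "SSP3-7.0": 0.8, "SSP5-8.5": 1.0},
    "2050s": {"SSP1-2.6": 0.9, "SSP2-4.5": 1.3, "SSP3-7.0": 1.6, "SSP5-8.5": 2.0},
    "2070s": {"SSP1-2.6": 1.1, "SSP2-4.5": 1.9, "SSP3-7.0": 2.6, "SSP5-8.5": 3.4},
    "2090s": {"SSP1-2.6": 1.2, "SSP2-4.5": 2.4, "SSP3-7.0": 3.7, "SSP5-8.5": 5.0},
}


@dataclass
class ClimateGrid:
    """Regular lon/lat raster stack of named climate covariates.

    Cell-center registered, north-up storage with ``lat_centers`` ascending,
    longitudes in [-180, 180). ``period == "current"`` if and only if
    ``scenario == "none"``.
    """

    lon_centers: np.ndarray
    lat_centers: np.ndarray
    covariates: dict[str, np.ndarray]
    period: str = CURRENT_PERIOD
    scenario: str = NO_SCENARIO

    def __post_init__(self):
        self.lon_centers = np.asarray(self.lon_centers, dtype=float)
        self.lat_centers = np.asarray(self.lat_centers, dtype=float)
        if self.lon_centers.size == 0 or self.lat_centers.size == 0:
            raise InvalidExtentError("grid has zero cells")
        if self.lat_centers.size > 1 and not np.all(np.diff(self.lat_centers) > 0):
            raise InvalidConfigError("lat_centers must be strictly ascending")
        shape = self.shape
        for name, layer in self.covariates.items():
            layer = np.asarray(layer, dtype=float)
            if layer.shape != shape:
                raise InvalidConfigError(
                    f"covariate {name!r} has shape {layer.shape}, expected {shape}"
                )
            self.covariates[name] = layer
        if (self.period == CURRENT_PERIOD) != (self.scenario == NO_SCENARIO):
            raise InvalidConfigError(
                "period 'current' must pair with scenario 'none' and vice versa"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat_centers.size, self.lon_centers.size)

    @property
    def n_cells(self) -> int:
        return self.lat_centers.size * self.lon_centers.size

    @property
    def resolution(self) -> float:
        """Degrees per cell (assumed equal in lon and lat)."""
        if self.lat_centers.size > 1:
            return float(self.lat_centers[1] - self.lat_centers[0])
        if self.lon_centers.size > 1:
            return float(self.lon_centers[1] - self.lon_centers[0])
        return 1.0

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariates)

    def covariate_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Stack covariates as an (n_cells, n_covariates) design matrix.

        Cells are flattened in C order (lat-major), matching ``np.ravel`` on
        the 2-D layers.
        """
        names = list(self.covariates) if names is None else names
        missing = [n for n in names if n not in self.covariates]
        if missing:
            raise KeyError(f"missing covariate layer(s): {missing}")
        return np.column_stack([self.covariates[n].ravel() for n in names])

    def cell_index(self, lon, lat) -> np.ndarray:
        """Flat cell index for coordinates; -1 for points outside the extent."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        res = self.resolution
        col = np.floor((lon - (self.lon_centers[0] - res / 2)) / res).astype(int)
        row = np.floor((lat - (self.lat_centers[0] - res / 2)) / res).astype(int)
        ok = (col >= 0) & (col < self.lon_centers.size) & (row >= 0) & (row < self.lat_centers.size)
        idx = np.where(ok, row * self.lon_centers.size + col, -1)
        return idx

    def cell_center(self, flat_index) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) centers for flat cell indices."""
        flat_index = np.asarray(flat_index, dtype=int)
        row, col = np.divmod(flat_index, self.lon_centers.size)
        return self.lon_centers[col], self.lat_centers[row]

    def same_grid(self, other: "ClimateGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.lon_centers, other.lon_centers)
            and np.allclose(self.lat_centers, other.lat_centers)
        )

    def replace(self, **kwargs) -> "ClimateGrid":
        return dataclasses.replace(self, **kwargs)


@dataclass
class VirtualSpecies:
    """Simulated species with a known suitability surface and true range."""

    species_id: str
    response_params: dict[str, tuple[float, float]]  # covariate -> (optimum, tolerance)
    suitability_true: np.ndarray  # (n_lat, n_lon) in [0, 1]
    range_true: np.ndarray  # boolean occupancy, same shape


@dataclass
class OccurrenceSet:
    """Presence-only records for one species, optionally with taxonomy."""

    species_id: str
    records: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))  # (n, 2) lon, lat
    genus: str | None = None
    family: str | None = None

    def __post_init__(self):
        self.records = np.asarray(self.records, dtype=float).reshape(-1, 2)
        if np.isnan(self.records).any():
            raise InvalidParameterError(f"{self.species_id}: NaN coordinates")

    @property
    def n_records(self) -> int:
        return self.records.shape[0]


def _smooth_field(shape, correlation_length, rng) -> np.ndarray:
    """Gaussian random field via smoothed white noise, unit variance."""
    noise = rng.standard_normal(shape)
    if correlation_length > 0:
        noise = gaussian_filter(noise, sigma=correlation_length, mode="nearest")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
    return noise


def _validate_warming(warming: dict, periods, scenarios) -> None:
    for p in periods:
        if p not in warming:
            raise InvalidConfigError(f"warming table missing period {p!r}")
        for s in scenarios:
            if s not in warming[p]:
                raise InvalidConfigError(f"warming table missing scenario {s!r} in {p!r}")
            if warming[p][s] < 0:
                raise InvalidConfigError("warming increments must be nonnegative")
    # nondecreasing across periods for each scenario, and across scenarios per period
    for s in scenarios:
        vals = [warming[p][s] for p in periods]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise InvalidConfigError(f"warming not nondecreasing over periods for {s!r}")
    for p in periods:
        vals = [warming[p][s] for s in scenarios]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise InvalidConfigError(f"warming not nondecreasing over scenarios in {p!r}")


def generate_climate(
    extent: tuple[float, float, float, float],
    resolution: float,
    n_covariates: int = 4,
    warming: dict | None = None,
    noise_amplitude: float = 0.3,
    correlation_length: float = 3.0,
    temperature_gradient: float = 1.0,
    temperature_at_equator: float = 25.0,
    seed: int | None = 0,
    periods=PERIODS,
    scenarios=SCENARIOS,
) -> list[ClimateGrid]:
    """Generate one current grid plus a future period x scenario matrix.

    Parameters
    ----------
    extent
        (lon_min, lon_max, lat_min, lat_max) in degrees; cells are laid out
        with centers offset half a cell from the edges.
    resolution
        Cell size in degrees (> 0).
    n_covariates
        Number of covariate layers (>= 1). Layer 0 is temperature-like with a
        poleward (decreasing with latitude) gradient; layer 1 precipitation-like;
        further layers are independent smooth fields.
    warming
        Nested mapping ``{period: {scenario: degC}}`` of nonnegative increments,
        nondecreasing across periods and scenarios. Only the temperature layer
        is modified in future grids.
    noise_amplitude
        Standard deviation of the spatially correlated noise added to future
        temperature layers (0 disables noise).

    Returns
    -------
    list of ClimateGrid
        The current grid first, then one grid per (period, scenario) pair:
        ``1 + len(periods) * len(scenarios)`` grids (17 with defaults).
    """
    if resolution <= 0:
        raise InvalidConfigError("resolution must be positive")
    if n_covariates < 1:
        raise InvalidConfigError("need at least one covariate")
    lon_min, lon_max, lat_min, lat_max = extent
    n_lon = int(round((lon_max - lon_min) / resolution))
    n_lat = int(round((lat_max - lat_min) / resolution))
    if n_lon < 1 or n_lat < 1:
        raise InvalidExtentError(f"extent {extent} yields zero cells at {resolution} deg")
    if warming is None:
        warming = DEFAULT_WARMING
    _validate_warming(warming, periods, scenarios)

    rng = np.random.default_rng(seed)
    lon_centers = lon_min + resolution * (np.arange(n_lon) + 0.5)
    lat_centers = lat_min + resolution * (np.arange(n_lat) + 0.5)
    shape = (n_lat, n_lon)

    lat2d = np.broadcast_to(lat_centers[:, None], shape)
    temp = temperature_at_equator - temperature_gradient * lat2d
    temp = temp + 0.5 * _smooth_field(shape, correlation_length, rng)

    covs = {"temperature": temp}
    if n_covariates >= 2:
        covs["precipitation"] = 500.0 + 150.0 * _smooth_field(shape, correlation_length, rng)
    for i in range(2, n_covariates):
        covs[f"cov{i + 1}"] = _smooth_field(shape, correlation_length, rng)

    current = ClimateGrid(lon_centers, lat_centers, dict(covs))
    grids = [current]
    for p in periods:
        for s in scenarios:
            fut = {k: v.copy() for k, v in covs.items()}
            noise = (
                noise_amplitude * _smooth_field(shape, correlation_length, rng)
                if noise_amplitude > 0
                else 0.0
            )
            fut["temperature"] = fut["temperature"] + warming[p][s] + noise
            grids.append(ClimateGrid(lon_centers, lat_centers, fut, period=p, scenario=s))
    return grids


def gaussian_suitability(
    grid: ClimateGrid, response_params: dict[str, tuple[float, float]]
) -> np.ndarray:
    """Product of per-covariate Gaussian responses exp(-(x-opt)^2 / (2 tol^2))."""
    suit = np.ones(grid.shape)
    for name, (opt, tol) in response_params.items():
        if tol <= 0:
            raise InvalidParameterError(f"tolerance for {name!r} must be > 0")
        x = grid.covariates[name]
        suit = suit * np.exp(-((x - opt) ** 2) / (2.0 * tol**2))
    return suit


def generate_virtual_species(
    climate_current: ClimateGrid,
    n_species: int,
    occupancy_cutoff: float = 0.5,
    response_params: list[dict[str, tuple[float, float]]] | None = None,
    optimum_quantiles: tuple[float, float] = (0.2, 0.8),
    tolerance_range: tuple[float, float] = (0.8, 1.6),
    seed: int | None = 0,
) -> list[VirtualSpecies]:
    """Create virtual species with Gaussian response surfaces on the current grid.

    When ``response_params`` is omitted, each species draws a per-covariate
    optimum uniformly between the layer's ``optimum_quantiles`` values and a
    tolerance uniform in ``tolerance_range`` times the layer's standard
    deviation. The true range is ``suitability >= occupancy_cutoff``.
    """
    if not 0 < occupancy_cutoff < 1:
        raise InvalidParameterError("occupancy_cutoff must be in (0, 1)")
    if n_species < 1:
        raise InvalidParameterError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_species):
        if response_params is not None:
            params = response_params[i]
        else:
            params = {}
            for name, layer in climate_current.covariates.items():
                lo, hi = np.quantile(layer, optimum_quantiles)
                opt = float(rng.uniform(lo, hi))
                tol = float(rng.uniform(*tolerance_range) * max(layer.std(), 1e-9))
                params[name] = (opt, tol)
        suit = gaussian_suitability(climate_current, params)
        out.append(
            VirtualSpecies(
                species_id=f"vsp{i:04d}",
                response_params=params,
                suitability_true=suit,
                range_true=suit >= occupancy_cutoff,
            )
        )
    return out


def sample_occurrences(
    species: VirtualSpecies,
    grid: ClimateGrid,
    n_records: int,
    bias_field: np.ndarray | None = None,
    genus: str | None = None,
    family: str | None = None,
    seed: int | None = 0,
) -> OccurrenceSet:
    """Draw presence-only records from a species' occupied cells.

    Cells are sampled with probability proportional to
    ``suitability_true * bias_field`` restricted to ``range_true``; each record
    is jittered uniformly within its cell (strictly inside the bounds).
    """
    if n_records < 0:
        raise InvalidParameterError("n_records must be >= 0")
    if n_records == 0:
        return OccurrenceSet(species.species_id, np.empty((0, 2)), genus=genus, family=family)
    occ = species.range_true.ravel()
    if not occ.any():
        raise NoHabitatError(f"{species.species_id}: empty true range")
    weights = species.suitability_true.ravel().astype(float).copy()
    if bias_field is not None:
        bias = np.asarray(bias_field, dtype=float).ravel()
        if bias.shape != weights.shape:
            raise InvalidParameterError("bias_field shape mismatch")
        if (bias < 0).any():
            raise InvalidParameterError("bias_field must be nonnegative")
        weights = weights * bias
    weights[~occ] = 0.0
    total = weights.sum()
    if total <= 0:
        raise NoHabitatError(f"{species.species_id}: zero total sampling weight")
    rng = np.random.default_rng(seed)
    cells = rng.choice(weights.size, size=n_records, replace=True, p=weights / total)
    lon_c, lat_c = grid.cell_center(cells)
    res = grid.resolution
    jitter = rng.uniform(-0.4999, 0.4999, size=(n_records, 2)) * res
    records = np.column_stack([lon_c + jitter[:, 0], lat_c + jitter[:, 1]])
    return OccurrenceSet(species.species_id, records, genus=genus, family=family)
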