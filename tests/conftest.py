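import numpy as np
import pytest

from floracast.prep import ModelingDataset, build_modeling_dataset
from floracast.synthetic import (
    ClimateGrid,
    VirtualSpecies,
    generate_climate,
    generate_virtual_species,
    sample_occurrences,
)

EXTENT = (-15.0, 15.0, 55.0, 75.0)  # 30 lon x 20 lat cells at 1 degree


@pytest.fixture(scope="session")
def grids17():
    """One current + 16 future grids on a small Arctic-like window."""
    return generate_climate(EXTENT, resolution=1.0, seed=7)


@pytest.fixture(scope="session")
def current_grid(grids17):
    return grids17[0]


@pytest.fixture(scope="session")
def species_small(current_grid):
    """Three virtual species with temperature-dominated responses."""
    t = current_grid.covariates["temperature"]
    params = []
    for frac in (0.35, 0.5, 0.65):
        opt = float(np.quantile(t, frac))
        p = {"temperature": (opt, 2.5)}
        for name, layer in current_grid.covariates.items():
            if name != "temperature":
                p[name] = (float(layer.mean()), 5.0 * float(layer.std()))
        params.append(p)
    return generate_virtual_species(
        current_grid, 3, occupancy_cutoff=0.5, response_params=params, seed=3
    )


@pytest.fixture(scope="session")
def occurrences_small(species_small, current_grid):
    return [
        sample_occurrences(vs, current_grid, 80, seed=100 + i)
        for i, vs in enumerate(species_small)
    ]


@pytest.fixture(scope="session")
def dataset_small(occurrences_small, current_grid):
    return build_modeling_dataset(occurrences_small[0], current_grid, seed=5)


@pytest.fixture
def separable_dataset():
    """1-D linearly separable presences vs background."""
    rng = np.random.default_rng(0)
    Xp = rng.normal(5.0, 0.3, size=(60, 1))
    Xb = rng.normal(0.0, 0.3, size=(200, 1))
    return ModelingDataset(
        species_id="sep",
        presence_cells=np.arange(60),
        background_cells=np.arange(1000, 1200),
        X_presence=Xp,
        X_background=Xb,
        covariate_names=["x"],
    )


def tiny_grid(values_by_name, lon0=0.5, lat0=60.5, res=1.0, period="current", scenario="none"):
    """Build a ClimateGrid from explicit 2-D covariate arrays."""
    first = next(iter(values_by_name.values()))
    arr = np.asarray(first, dtype=float)
    n_lat, n_lon = arr.shape
    return ClimateGrid(
        lon_centers=lon0 + res * np.arange(n_lon),
        lat_centers=lat0 + res * np.arange(n_lat),
        covariates={k: np.asarray(v, dtype=float) for k, v in values_by_name.items()},
        period=period,
        scenario=scenario,
    )


def make_virtual(suitability, cutoff=0.5, species_id="v"):
    suit = np.asarray(suitability, dtype=float)
    return VirtualSpecies(
        species_id=species_id,
        response_params={},
        suitability_true=suit,
        range_true=suit >= cutoff,
    )
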