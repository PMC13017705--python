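"""Readers and writers: ESRI ASCII rasters, occurrence CSV, model JSON.

Rasters use the plain-text ESRI ASCII grid format (.asc) so every artifact is
human-readable and diffable; GeoTIFF support would only add a binary
dependency. All grids are north-up, cell-center registered, EPSG:4326
semantics with longitudes in [-180, 180).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import EnsembleModel
from .errors import InvalidConfigError
from .synthetic import ClimateGrid, OccurrenceSet


def write_ascii_grid(path, array, lon_centers, lat_centers, fmt: str = "%.6g") -> None:
    """Write a 2-D layer as an ESRI ASCII grid (rows north to south)."""
    array = np.asarray(array)
    lon_centers = np.asarray(lon_centers, dtype=float)
    lat_centers = np.asarray(lat_centers, dtype=float)
    if lat_centers.size > 1:
        res = lat_centers[1] - lat_centers[0]
    elif lon_centers.size > 1:
        res = lon_centers[1] - lon_centers[0]
    else:
        res = 1.0
    header = (
        f"ncols {array.shape[1]}\n"
        f"nrows {array.shape[0]}\n"
        f"xllcorner {lon_centers[0] - res / 2:.10g}\n"
        f"yllcorner {lat_centers[0] - res / 2:.10g}\n"
        f"cellsize {res:.10g}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, array[::-1], fmt=fmt)  # storage is south-up internally


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (array, lon_centers, lat_centers)."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        array = np.loadtxt(fh, ndmin=2)[::-1]
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if array.shape != (nrows, ncols):
        raise InvalidConfigError(f"{path}: data shape {array.shape} != header ({nrows},{ncols})")
    res = header["cellsize"]
    lon = header["xllcorner"] + res * (np.arange(ncols) + 0.5)
    lat = header["yllcorner"] + res * (np.arange(nrows) + 0.5)
    return array, lon, lat


def _grid_tag(period: str, scenario: str) -> str:
    return f"{period}__{scenario}".replace("/", "_")


def write_climate_dir(grids: list[ClimateGrid], out_dir) -> Path:
    """Write one .asc per covariate per grid plus an index.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = []
    for g in grids:
        tag = _grid_tag(g.period, g.scenario)
        files = {}
        for name, layer in g.covariates.items():
            fname = f"{tag}__{name}.asc"
            write_ascii_grid(out_dir / fname, layer, g.lon_centers, g.lat_centers, fmt="%.10g")
            files[name] = fname
        index.append({"period": g.period, "scenario": g.scenario, "covariates": files})
    write_json(out_dir / "index.json", index)
    return out_dir


def read_climate_dir(climate_dir) -> list[ClimateGrid]:
    climate_dir = Path(climate_dir)
    index = read_json(climate_dir / "index.json")
    grids = []
    for entry in index:
        covs, lon, lat = {}, None, None
        for name, fname in entry["covariates"].items():
            covs[name], lon, lat = read_ascii_grid(climate_dir / fname)
        grids.append(
            ClimateGrid(lon, lat, covs, period=entry["period"], scenario=entry["scenario"])
        )
    return grids


def write_occurrences_csv(path, occurrence_sets: list[OccurrenceSet]) -> None:
    """Long-format CSV: species,lon,lat,genus,family (one row per record).

    Species with zero records still get a row with empty coordinates so the
    checklist round-trips.
    """
    rows = []
    for o in occurrence_sets:
        if o.n_records == 0:
            rows.append({"species": o.species_id, "lon": np.nan, "lat": np.nan,
                         "genus": o.genus, "family": o.family})
        for lon, lat in o.records:
            rows.append({"species": o.species_id, "lon": lon, "lat": lat,
                         "genus": o.genus, "family": o.family})
    pd.DataFrame(rows, columns=["species", "lon", "lat", "genus", "family"]).to_csv(
        path, index=False
    )


def read_occurrences_csv(path) -> list[OccurrenceSet]:
    df = pd.read_csv(path)
    out = []
    for sp, grp in df.groupby("species", sort=True):
        recs = grp[["lon", "lat"]].dropna().to_numpy(dtype=float)
        genus = grp["genus"].iloc[0] if "genus" in grp and pd.notna(grp["genus"].iloc[0]) else None
        family = (
            grp["family"].iloc[0] if "family" in grp and pd.notna(grp["family"].iloc[0]) else None
        )
        out.append(OccurrenceSet(str(sp), recs, genus=genus, family=family))
    return out


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_models_json(path, models: list[EnsembleModel]) -> None:
    write_json(path, {"version": "1", "models": [m.to_dict() for m in models]})


def read_models_json(path) -> list[EnsembleModel]:
    doc = read_json(path)
    return [EnsembleModel.from_dict(d) for d in doc["models"]]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
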