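"""End-to-end driver: simulate -> prep -> fit -> project -> metrics -> richness -> report.

Each stage reads its inputs from the output directory and writes its own
outputs there, so deleting an intermediate and re-running regenerates that
stage and everything downstream. All randomness derives from the single
config seed via fixed per-stage offsets, making reruns bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .change import summarize_change
from .ensemble import fit_species_ensemble, LEARNER_KINDS
from .errors import FloracastError, UnmodelableSpeciesError
from .prep import build_modeling_dataset, filter_min_occurrences
from .projection import RangeMap, make_range_map, project_species, grid_cell_areas
from .richness import (
    DEFAULT_SECTOR_BANDS,
    SectorMask,
    mean_species_richness,
    sector_summary,
    stack_richness,
)
from .synthetic import (
    DEFAULT_WARMING,
    PERIODS,
    SCENARIOS,
    generate_climate,
    generate_virtual_species,
    sample_occurrences,
)

logger = logging.getLogger(__name__)

# seed offsets per randomness consumer; fixed so stages rerun identically
_SEED_CLIMATE = 11
_SEED_SPECIES = 23
_SEED_OCC = 1_000
_SEED_BG = 100_000
_SEED_FIT = 200_000


@dataclass
class PipelineConfig:
    """All knobs for a synthetic end-to-end run."""

    extent: tuple[float, float, float, float] = (-30.0, 30.0, 50.0, 80.0)
    resolution: float = 1.0
    n_covariates: int = 4
    periods: tuple[str, ...] = PERIODS
    scenarios: tuple[str, ...] = SCENARIOS
    warming: dict = field(default_factory=lambda: {p: dict(s) for p, s in DEFAULT_WARMING.items()})
    noise_amplitude: float = 0.2
    correlation_length: float = 3.0
    n_species: int = 30
    n_records_per_species: int = 60
    occupancy_cutoff: float = 0.5
    min_records: int = 25
    n_folds: int = 5
    auc_cutoff: float = 0.7
    learner_kinds: tuple[str, ...] = LEARNER_KINDS
    stability_band: float = 0.05
    sector_bands: list = field(default_factory=lambda: [list(b) for b in DEFAULT_SECTOR_BANDS])
    write_suitability: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["extent"] = list(self.extent)
        d["periods"] = list(self.periods)
        d["scenarios"] = list(self.scenarios)
        d["learner_kinds"] = list(self.learner_kinds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("extent", "periods", "scenarios", "learner_kinds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(fio.read_json(path))


# ---------------------------------------------------------------- stages


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    grids = generate_climate(
        cfg.extent,
        cfg.resolution,
        n_covariates=cfg.n_covariates,
        warming=cfg.warming,
        noise_amplitude=cfg.noise_amplitude,
        correlation_length=cfg.correlation_length,
        seed=cfg.seed + _SEED_CLIMATE,
        periods=cfg.periods,
        scenarios=cfg.scenarios,
    )
    current = grids[0]
    species = generate_virtual_species(
        current,
        cfg.n_species,
        occupancy_cutoff=cfg.occupancy_cutoff,
        seed=cfg.seed + _SEED_SPECIES,
    )
    occ_sets = []
    for i, vs in enumerate(species):
        n = int(cfg.n_records_per_species)
        occ = sample_occurrences(
            vs,
            current,
            n,
            genus=f"genus{i % max(1, cfg.n_species // 3):03d}",
            family=f"family{i % max(1, cfg.n_species // 6):03d}",
            seed=cfg.seed + _SEED_OCC + i,
        )
        occ_sets.append(occ)
    fio.write_climate_dir(grids, out / "climate")
    fio.write_occurrences_csv(out / "occurrences.csv", occ_sets)
    # ground truth for validation studies
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    for vs in species:
        fio.write_ascii_grid(
            truth_dir / f"{vs.species_id}__range_true.asc",
            vs.range_true.astype(int),
            current.lon_centers,
            current.lat_centers,
            fmt="%d",
        )


def stage_prep(cfg: PipelineConfig, out: Path) -> None:
    occ_sets = fio.read_occurrences_csv(out / "occurrences.csv")
    retained, report = filter_min_occurrences(occ_sets, cfg.min_records)
    fio.write_json(out / "coverage.json", report.to_dict())
    (out / "retained_species.txt").write_text(
        "".join(f"{o.species_id}\n" for o in retained)
    )
    logger.info("prep: %s", report.summary_line())


def stage_fit(cfg: PipelineConfig, out: Path) -> None:
    occ_sets = {o.species_id: o for o in fio.read_occurrences_csv(out / "occurrences.csv")}
    retained = (out / "retained_species.txt").read_text().split()
    grids = fio.read_climate_dir(out / "climate")
    current = next(g for g in grids if g.period == "current")
    models, skipped = [], []
    for i, sp in enumerate(retained):
        ds = build_modeling_dataset(occ_sets[sp], current, seed=cfg.seed + _SEED_BG + i)
        try:
            model = fit_species_ensemble(
                ds,
                n_folds=cfg.n_folds,
                auc_cutoff=cfg.auc_cutoff,
                kinds=cfg.learner_kinds,
                seed=cfg.seed + _SEED_FIT + i,
            )
        except UnmodelableSpeciesError as exc:
            logger.warning("fit: %s", exc)
            skipped.append(sp)
            continue
        models.append(model)
    fio.write_models_json(out / "models.json", models)
    fio.write_json(out / "unmodelable.json", skipped)
    logger.info("fit: %d models, %d unmodelable", len(models), len(skipped))


def stage_project(cfg: PipelineConfig, out: Path) -> None:
    models = fio.read_models_json(out / "models.json")
    grids = fio.read_climate_dir(out / "climate")
    maps_dir = out / "maps"
    maps_dir.mkdir(exist_ok=True)
    rows = []
    for model in models:
        for rm in project_species(model, grids):
            tag = f"{rm.species_id}__{rm.period}__{rm.scenario}"
            occ_file = f"{tag}__occupancy.asc"
            fio.write_ascii_grid(
                maps_dir / occ_file,
                rm.occupancy.astype(int),
                rm.lon_centers,
                rm.lat_centers,
                fmt="%d",
            )
            if cfg.write_suitability:
                fio.write_ascii_grid(
                    maps_dir / f"{tag}__suitability.asc",
                    rm.suitability,
                    rm.lon_centers,
                    rm.lat_centers,
                )
            rows.append(
                {
                    "species": rm.species_id,
                    "period": rm.period,
                    "scenario": rm.scenario,
                    "threshold": rm.threshold,
                    "aoh_km2": rm.aoh_km2,
                    "occupancy_file": occ_file,
                }
            )
    pd.DataFrame(rows).to_csv(maps_dir / "manifest.csv", index=False)
    logger.info("project: wrote %d maps (%d species x %d grids)",
                len(rows), len(models), len(grids))


def _load_range_maps(out: Path) -> list[RangeMap]:
    maps_dir = out / "maps"
    manifest = pd.read_csv(maps_dir / "manifest.csv")
    maps = []
    for row in manifest.itertuples():
        occ, lon, lat = fio.read_ascii_grid(maps_dir / row.occupancy_file)
        occ = occ.astype(bool)
        rm = RangeMap(
            species_id=row.species,
            period=row.period,
            scenario=row.scenario,
            lon_centers=lon,
            lat_centers=lat,
            suitability=occ.astype(float),  # suitability not persisted by default
            occupancy=occ,
            threshold=row.threshold,
            aoh_km2=float(row.aoh_km2),
        )
        maps.append(rm)
    return maps


def stage_metrics(cfg: PipelineConfig, out: Path) -> None:
    maps = _load_range_maps(out)
    by_species: dict[str, dict[tuple[str, str], RangeMap]] = {}
    for m in maps:
        by_species.setdefault(m.species_id, {})[(m.period, m.scenario)] = m
    rows = []
    for sp, d in sorted(by_species.items()):
        now = d[("current", "none")]
        for (period, scenario), fut in sorted(d.items()):
            if period == "current":
                continue
            s = summarize_change(now, fut, cfg.stability_band)
            row = s.to_dict()
            for key in ("centroid_now", "centroid_future"):
                c = row.pop(key)
                row[f"{key}_lon"] = None if c is None else c[0]
                row[f"{key}_lat"] = None if c is None else c[1]
            rows.append(row)
    pd.DataFrame(rows).to_csv(out / "change_summaries.csv", index=False)
    logger.info("metrics: %d change rows", len(rows))


def stage_richness(cfg: PipelineConfig, out: Path) -> None:
    maps = _load_range_maps(out)
    by_ps: dict[tuple[str, str], list[RangeMap]] = {}
    for m in maps:
        by_ps.setdefault((m.period, m.scenario), []).append(m)
    rich_dir = out / "richness"
    rich_dir.mkdir(exist_ok=True)
    msr = {}
    for (period, scenario), group in sorted(by_ps.items()):
        rmap = stack_richness(group)
        fio.write_ascii_grid(
            rich_dir / f"richness__{period}__{scenario}.asc",
            rmap.counts,
            rmap.lon_centers,
            rmap.lat_centers,
            fmt="%d",
        )
        msr[f"{period}__{scenario}"] = mean_species_richness(rmap)
    fio.write_json(rich_dir / "msr.json", msr)
    logger.info("richness: %d surfaces", len(by_ps))


def stage_report(cfg: PipelineConfig, out: Path) -> None:
    from .change import ChangeSummary
    from .richness import RichnessMap

    df = pd.read_csv(out / "change_summaries.csv")
    summaries = []
    for row in df.itertuples():
        c_now = (
            None
            if pd.isna(row.centroid_now_lon)
            else (float(row.centroid_now_lon), float(row.centroid_now_lat))
        )
        c_fut = (
            None
            if pd.isna(row.centroid_future_lon)
            else (float(row.centroid_future_lon), float(row.centroid_future_lat))
        )
        summaries.append(
            ChangeSummary(
                species_id=row.species_id,
                period=row.period,
                scenario=row.scenario,
                aoh_now_km2=row.aoh_now_km2,
                aoh_future_km2=row.aoh_future_km2,
                delta_km2=row.delta_km2,
                fold_change=None if pd.isna(row.fold_change) else float(row.fold_change),
                change_class=None if pd.isna(row.change_class) else row.change_class,
                extinct_flag=bool(row.extinct_flag),
                centroid_now=c_now,
                centroid_future=c_fut,
                dlat=None if pd.isna(row.dlat) else float(row.dlat),
                dlon=None if pd.isna(row.dlon) else float(row.dlon),
                shift_km=None if pd.isna(row.shift_km) else float(row.shift_km),
                direction_class=None if pd.isna(row.direction_class) else row.direction_class,
            )
        )
    rich_dir = out / "richness"
    richness_maps = {}
    for f in sorted(rich_dir.glob("richness__*.asc")):
        _, period, scenario = f.stem.split("__")
        counts, lon, lat = fio.read_ascii_grid(f)
        richness_maps[(period, scenario)] = RichnessMap(
            counts.astype(int), period, scenario, lon, lat
        )
    grids = fio.read_climate_dir(out / "climate")
    current = next(g for g in grids if g.period == "current")
    mask = SectorMask.from_lon_bands(current, [tuple(b) for b in cfg.sector_bands])
    maps_now = {}
    report = sector_summary(maps_now, summaries, richness_maps, mask)
    report.to_csv(out / "sector_summary.csv", index=False)
    fio.write_json(
        out / "sector_summary.json", report.to_dict(orient="records")
    )
    logger.info("report: %d sector rows", len(report))


_STAGES = [
    ("simulate", stage_simulate, ["occurrences.csv", "climate/index.json"]),
    ("prep", stage_prep, ["coverage.json", "retained_species.txt"]),
    ("fit", stage_fit, ["models.json"]),
    ("project", stage_project, ["maps/manifest.csv"]),
    ("metrics", stage_metrics, ["change_summaries.csv"]),
    ("richness", stage_richness, ["richness/msr.json"]),
    ("report", stage_report, ["sector_summary.csv"]),
]

STAGE_NAMES = [name for name, _, _ in _STAGES]


def run_pipeline(
    cfg: PipelineConfig,
    out_dir,
    force: bool = False,
    stages: list[str] | None = None,
) -> Path:
    """Run all (or selected) stages, regenerating missing outputs and downstream.

    Returns the output directory. A manifest.json records every output file
    with its SHA-256 and the config (including all seeds).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fio.write_json(out / "config.json", cfg.to_dict())
    upstream_ran = False
    for name, fn, sentinels in _STAGES:
        if stages is not None:
            if name in stages:
                t0 = time.time()
                try:
                    fn(cfg, out)
                except FloracastError as exc:
                    raise FloracastError(f"stage {name!r} failed: {exc}") from exc
                logger.info("stage %s: %.1fs", name, time.time() - t0)
            continue
        missing = [s for s in sentinels if not (out / s).exists()]
        if force or missing or upstream_ran:
            t0 = time.time()
            try:
                fn(cfg, out)
            except FloracastError as exc:
                raise FloracastError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: %.1fs", name, time.time() - t0)
            upstream_ran = True
        else:
            logger.info("stage %s: outputs present, skipped", name)
    manifest = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "files": {
            str(p.relative_to(out)): fio.sha256_file(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    fio.write_json(out / "manifest.json", manifest)
    return out
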