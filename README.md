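# floracast

Ensemble species distribution modelling (SDM) under future climate
scenarios, with a virtual-species synthetic-data module that gives every
stage known ground truth.

The pipeline models how a regional flora responds to climate change:

1. **simulate** — synthetic climate grids (1 current + 4 future periods x
   4 SSP emission scenarios = 17 grids), virtual species with Gaussian
   response surfaces and known true ranges, and presence-only occurrence
   samples drawn with configurable spatial bias.
2. **prep** — minimum-occurrence filtering (strictly more than 25 records by
   default) with a taxonomic coverage report, thinning to one presence per
   grid cell, and uniform background (pseudo-absence) sampling.
3. **fit** — five suitability learners per species (percentile envelope,
   Mahalanobis distance, quadratic logistic regression, distance-weighted
   k-NN, gradient-boosted stumps), screened by cross-validated AUC and
   combined with weights proportional to max(AUC − 0.5, 0); binarization by
   the max-TSS threshold.
4. **project** — each ensemble projected onto all 17 climates (covariates
   clamped to the training range), giving 17 binary range maps per species
   and their areas of habitat (AOH, spherical km²).
5. **metrics** — per species x scenario: AOH delta, expansion / contraction /
   stable classes (±5% stability band), fold change, extinction flags, and
   centroid migration vectors (area-weighted spherical centroids, haversine
   distances, antimeridian-safe longitudes).
6. **richness** — stacked species richness surfaces and mean species
   richness (MSR, species per grid cell).
7. **report** — per-sector roll-ups over a longitude-band sector mask.

All rasters are plain-text ESRI ASCII grids (north-up, cell-center
registered, EPSG:4326 semantics); tables are CSV and JSON. No binary
formats are produced or required.

## CLI

```sh
# full synthetic run, end to end
floracast run-all --out out/demo --seed 1

# or stage by stage (each stage reads the previous stage's outputs)
floracast simulate --config config.json --out out/demo
floracast prep     --config config.json --out out/demo
floracast fit      --config config.json --out out/demo
floracast project  --config config.json --out out/demo
floracast metrics  --config config.json --out out/demo
floracast richness --config config.json --out out/demo
floracast report   --config config.json --out out/demo
```

`--config` takes a JSON file with any subset of the `PipelineConfig`
fields (extent, resolution, species counts, warming table, AUC cutoff,
stability band, sector bands, seed, ...). Re-running `run-all` skips stages
whose outputs exist; deleting an intermediate regenerates it and everything
downstream. `manifest.json` lists every output file with its SHA-256 and the
seeds used.

## Library use

```python
from floracast import (
    generate_climate, generate_virtual_species, sample_occurrences,
    build_modeling_dataset, fit_species_ensemble, project_species,
    summarize_change, stack_richness, mean_species_richness,
)

grids = generate_climate((-20, 20, 55, 75), resolution=0.5, seed=1)
species = generate_virtual_species(grids[0], n_species=10, seed=1)
occ = sample_occurrences(species[0], grids[0], 100, seed=1)
ds = build_modeling_dataset(occ, grids[0], seed=1)
model = fit_species_ensemble(ds, seed=1)
maps = project_species(model, grids)          # 17 range maps
change = summarize_change(maps[0], maps[-1])  # AOH change + migration vector
```

## Notes

- The five learner kinds are chosen to span envelope, parametric and
  nonparametric families, in the spirit of standard multi-algorithm SDM
  ensembles; any subset can be disabled via `learner_kinds`.
- MSR is unweighted per grid cell; an area-weighted variant is available via
  `mean_species_richness(..., area_weighted=True)`.
- Species whose projected future AOH is zero are flagged extinct and
  excluded from centroid statistics; species whose current AOH is zero are
  reported separately (undefined baseline).
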