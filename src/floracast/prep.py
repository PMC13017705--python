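"""Occurrence preparation: record-count filter, grid thinning, background points.

Produces the per-species modelling dataset (presence + background cells with
their covariate rows) and a taxonomic coverage report for the checklist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from ._utils import round_half_up
from .errors import InvalidParameterError, NoBackgroundError, NoUsableRecordsError
from .synthetic import ClimateGrid, OccurrenceSet

logger = logging.getLogger(__name__)


@dataclass
class CoverageReport:
    """Checklist-level accounting of the minimum-occurrence filter."""

    n_species_total: int
    n_species_retained: int
    pct_retained: float | None
    n_families_total: int
    n_families_covered: int
    pct_families: float | None
    n_genera_total: int
    n_genera_covered: int
    pct_genera: float | None

    def to_dict(self) -> dict:
        return asdict(self)

    def summary_line(self) -> str:
        return (
            f"retained {self.n_species_retained}/{self.n_species_total} species"
            f" ({self.pct_retained}%); families {self.n_families_covered}/"
            f"{self.n_families_total} ({self.pct_families}%); genera "
            f"{self.n_genera_covered}/{self.n_genera_total} ({self.pct_genera}%)"
        )


@dataclass
class ModelingDataset:
    """Presence/background cells and covariate rows for one species."""

    species_id: str
    presence_cells: np.ndarray  # flat grid indices, deduplicated, sorted
    background_cells: np.ndarray
    X_presence: np.ndarray  # (n_presence, n_cov)
    X_background: np.ndarray
    covariate_names: list[str]

    def __post_init__(self):
        if len(self.presence_cells) < 1:
            raise InvalidParameterError(f"{self.species_id}: no presence cells")
        if np.intersect1d(self.presence_cells, self.background_cells).size:
            raise InvalidParameterError(
                f"{self.species_id}: presence and background cells overlap"
            )

    @property
    def X(self) -> np.ndarray:
        """Stacked design matrix, presences first."""
        return np.vstack([self.X_presence, self.X_background])

    @property
    def y(self) -> np.ndarray:
        """Labels matching :attr:`X` (1 presence, 0 background)."""
        return np.concatenate(
            [np.ones(len(self.presence_cells)), np.zeros(len(self.background_cells))]
        )


def _pct(covered: int, total: int) -> float | None:
    if total == 0:
        return None
    return round_half_up(100.0 * covered / total, 1)


def filter_min_occurrences(
    occurrence_sets: list[OccurrenceSet], min_records: int = 25
) -> tuple[list[OccurrenceSet], CoverageReport]:
    """Keep species with strictly more than ``min_records`` records.

    Returns the retained sets and a :class:`CoverageReport` whose percentages
    are computed over the full input checklist and its taxonomy (half-up,
    one decimal). Species lacking taxonomy simply do not contribute to the
    family/genus tallies.
    """
    if min_records < 0:
        raise InvalidParameterError("min_records must be >= 0")
    retained = [o for o in occurrence_sets if o.n_records > min_records]

    families_all = {o.family for o in occurrence_sets if o.family is not None}
    genera_all = {o.genus for o in occurrence_sets if o.genus is not None}
    families_cov = {o.family for o in retained if o.family is not None}
    genera_cov = {o.genus for o in retained if o.genus is not None}

    report = CoverageReport(
        n_species_total=len(occurrence_sets),
        n_species_retained=len(retained),
        pct_retained=_pct(len(retained), len(occurrence_sets)),
        n_families_total=len(families_all),
        n_families_covered=len(families_cov),
        pct_families=_pct(len(families_cov), len(families_all)),
        n_genera_total=len(genera_all),
        n_genera_covered=len(genera_cov),
        pct_genera=_pct(len(genera_cov), len(genera_all)),
    )
    logger.info("filter_min_occurrences: %s", report.summary_line())
    return retained, report


def thin_to_grid(occurrence_set: OccurrenceSet, grid: ClimateGrid) -> np.ndarray:
    """Deduplicate records to one presence per grid cell.

    Records outside the grid extent are dropped (count logged). Returns
    sorted unique flat cell indices.
    """
    if occurrence_set.n_records == 0:
        raise NoUsableRecordsError(f"{occurrence_set.species_id}: no records")
    idx = grid.cell_index(occurrence_set.records[:, 0], occurrence_set.records[:, 1])
    n_outside = int((idx < 0).sum())
    if n_outside:
        logger.warning(
            "%s: dropped %d/%d records outside extent",
            occurrence_set.species_id,
            n_outside,
            occurrence_set.n_records,
        )
    inside = idx[idx >= 0]
    if inside.size == 0:
        raise NoUsableRecordsError(
            f"{occurrence_set.species_id}: all {occurrence_set.n_records} records outside extent"
        )
    return np.unique(inside)


def sample_background(
    grid: ClimateGrid,
    presence_cells: np.ndarray,
    n_background: int,
    seed: int | None = 0,
    land_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Uniform sample of non-presence cells, without replacement.

    The sample size is clamped to the number of available cells (with a
    warning). ``land_mask`` optionally restricts candidates (True = usable).
    """
    if n_background < 1:
        raise InvalidParameterError("n_background must be >= 1")
    usable = np.ones(grid.n_cells, dtype=bool)
    if land_mask is not None:
        usable &= np.asarray(land_mask, dtype=bool).ravel()
    usable[np.asarray(presence_cells, dtype=int)] = False
    available = np.flatnonzero(usable)
    if available.size == 0:
        raise NoBackgroundError("no cells available for background sampling")
    size = min(n_background, available.size)
    if size < n_background:
        logger.warning(
            "background clamped to %d (requested %d)", size, n_background
        )
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(available, size=size, replace=False))


def build_modeling_dataset(
    occurrence_set: OccurrenceSet,
    grid: ClimateGrid,
    n_background: int | None = None,
    background_cap: int = 10_000,
    seed: int | None = 0,
    land_mask: np.ndarray | None = None,
) -> ModelingDataset:
    """Thin records, draw background, and assemble covariate matrices.

    Default background size is 10x the presence count, capped at
    ``background_cap``.
    """
    presence = thin_to_grid(occurrence_set, grid)
    if n_background is None:
        n_background = min(10 * presence.size, background_cap)
    background = sample_background(grid, presence, n_background, seed=seed, land_mask=land_mask)
    X = grid.covariate_matrix()
    return ModelingDataset(
        species_id=occurrence_set.species_id,
        presence_cells=presence,
        background_cells=background,
        X_presence=X[presence],
        X_background=X[background],
        covariate_names=grid.covariate_names,
    )
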