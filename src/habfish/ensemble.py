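"""Technique ensembles and scenario summaries.

Each (species, scenario) has one biomass map per distribution-modelling
technique. The ensemble is the cellwise mean across techniques with
spread reported as 1 standard error (sample SD with n−1 denominator
over √n; configurable to plain SD). Study-area summaries average the
ensemble map over valid cells — water, and within the depth limit for
depth-restricted species — and scale to total biomass by the valid
area. Scenario effects are reported as percent change of the
area-mean density against the 0% baseline, computed on the ensemble
means (mean first, then ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .productivity import SpeciesParams
from .raster import RasterError, RasterGrid


@dataclass
class EnsembleSummary:
    """Area-wide biomass of one species under one scenario."""

    species: str
    scenario: float
    mean_density: float  # kg ha-1, mean over valid cells of ensemble mean
    se_density: float  # kg ha-1, 1 SE across techniques of the area mean
    total_biomass: float  # kg over the valid study area
    n_valid_cells: int
    area_ha: float


def technique_ensemble(
    maps: list[RasterGrid], use_se: bool = True
) -> tuple[RasterGrid, RasterGrid]:
    """Cellwise mean and SE (or SD) grids across technique maps.

    Nodata propagates: a cell that is NaN in any member is NaN in both
    outputs. At least two congruent maps are required.
    """
    if len(maps) < 2:
        raise ValueError(f"need >= 2 technique maps, got {len(maps)}")
    first = maps[0]
    for m in maps[1:]:
        first.require_congruent(m, "ensemble member")
    stack = np.stack([m.values for m in maps])
    any_nan = np.isnan(stack).any(axis=0)
    mean = np.where(any_nan, np.nan, stack.mean(axis=0))
    spread = stack.std(axis=0, ddof=1)
    if use_se:
        spread = spread / np.sqrt(len(maps))
    spread = np.where(any_nan, np.nan, spread)
    meta = {k: v for k, v in first.meta.items() if k != "technique"}
    mean_grid = RasterGrid(mean, first.cell_size, {**meta, "stat": "ensemble_mean"})
    se_grid = RasterGrid(
        spread, first.cell_size, {**meta, "stat": "ensemble_se" if use_se else "ensemble_sd"}
    )
    return mean_grid, se_grid


def area_mean(grid: RasterGrid) -> float:
    """Mean over valid (non-NaN) cells; errors on an all-nodata grid."""
    valid = grid.mask
    if not valid.any():
        raise RasterError("no valid cells to summarize")
    return float(grid.values[valid].mean())


def area_summary(
    mean_grid: RasterGrid,
    member_maps: list[RasterGrid],
    sp: SpeciesParams,
    scenario: float,
) -> EnsembleSummary:
    """Study-area summary row for one (species, scenario).

    ``mean_grid`` is the ensemble-mean biomass map, already depth-masked
    where the species requires it; ``member_maps`` are the per-technique
    maps used for the SE of the area mean (SD of the three per-technique
    area means over √3).
    """
    valid = mean_grid.mask
    if not valid.any():
        raise RasterError("no valid cells to summarize")
    n_valid = int(valid.sum())
    area_ha = n_valid * mean_grid.cell_area_ha
    mean_density = float(mean_grid.values[valid].mean())
    member_means = np.array([area_mean(m) for m in member_maps])
    se_density = float(member_means.std(ddof=1) / np.sqrt(len(member_means)))
    return EnsembleSummary(
        species=sp.name,
        scenario=scenario,
        mean_density=mean_density,
        se_density=se_density,
        total_biomass=mean_density * area_ha,
        n_valid_cells=n_valid,
        area_ha=area_ha,
    )


def relative_change(scenario_summary: EnsembleSummary, baseline_summary: EnsembleSummary) -> float:
    """Percent change of area-mean density against the 0% baseline."""
    if scenario_summary.species != baseline_summary.species:
        raise ValueError(
            f"species mismatch: {scenario_summary.species} vs {baseline_summary.species}"
        )
    if baseline_summary.scenario != 0:
        raise ValueError("baseline summary must be the 0% scenario")
    if baseline_summary.mean_density == 0:
        raise ZeroDivisionError("baseline mean density is zero")
    return 100.0 * (
        scenario_summary.mean_density - baseline_summary.mean_density
    ) / baseline_summary.mean_density


def summary_table(summaries: list[EnsembleSummary]) -> pd.DataFrame:
    """Tidy per-(species, scenario) table with relative change columns."""
    rows = []
    baselines = {s.species: s for s in summaries if s.scenario == 0}
    for s in summaries:
        base = baselines.get(s.species)
        rows.append(
            {
                "species": s.species,
                "scenario": s.scenario,
                "mean_kg_ha": s.mean_density,
                "se_kg_ha": s.se_density,
                "total_kg": s.total_biomass,
                "area_ha": s.area_ha,
                "rel_change_pct": (
                    relative_change(s, base) if base is not None else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).sort_values(["species", "scenario"]).reset_index(drop=True)
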