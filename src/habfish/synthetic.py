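"""Synthetic coastal landscapes, recruitment-habitat maps and monitoring data.

The real inputs to the pipeline are species-distribution-model outputs:
binary recruitment-habitat rasters for perch and pikeperch under seven
water-clarity (Secchi depth) scenarios, each produced by three modelling
techniques, on a coastal land/water grid with a depth layer — none of
which are distributable. This module generates stand-ins with the same
statistical structure:

* a coastal landscape with a connected land margin, islands, and depth
  increasing away from shore;
* spatially autocorrelated binary habitat whose prevalence responds
  positively (perch) or negatively (pikeperch) to relative Secchi-depth
  change, with the three technique variants being correlated
  perturbations of one shared latent field;
* noisy gill-net monitoring observations consistent with a CPUE map.

Mechanism: a latent Gaussian random field (white noise smoothed at the
configured autocorrelation range) is thresholded at the empirical
quantile matching the target prevalence. The scenario enters only as a
log-odds shift of prevalence — ``logit(p) = logit(base) + response ·
Δsecchi`` — on the *same* latent field, so one technique's habitat maps
are nested across scenario levels and prevalence is exactly monotone in
the scenario. Randomness is split per (species, technique) by hashing
labels against the master seed, so adding a scenario or species never
changes the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .raster import RasterGrid
from .scenarios import SCENARIO_LEVELS

TECHNIQUES = ("gam", "maxent", "rf")


class ConfigurationError(ValueError):
    """Invalid generator configuration or unknown label."""


@dataclass
class Landscape:
    """Water mask (1 water / 0 land), depth (m) and baseline Secchi (m).

    Depth and Secchi are NaN on land; both are strictly positive on
    water cells.
    """

    water_mask: RasterGrid
    depth: RasterGrid
    secchi_base: RasterGrid

    def __post_init__(self) -> None:
        self.water_mask.require_congruent(self.depth, "depth")
        self.water_mask.require_congruent(self.secchi_base, "secchi_base")

    @property
    def water(self) -> np.ndarray:
        return self.water_mask.values == 1.0


@dataclass
class HabitatGenConfig:
    """Knobs of the synthetic habitat generator.

    ``secchi_response`` is the shift in habitat log-odds per unit
    relative Secchi change (a +48% scenario contributes ``0.48 ·
    response``); its sign encodes each species' affinity — perch
    favours clear water (positive), pikeperch turbid (negative).
    """

    grid_size: int = 64
    cell_size: float = 250.0
    autocorrelation_range: float = 1500.0
    base_prevalence: dict = field(
        default_factory=lambda: {"perch": 0.30, "pikeperch": 0.15}
    )
    secchi_response: dict = field(
        default_factory=lambda: {"perch": 2.0, "pikeperch": -3.0}
    )
    technique_noise: float = 0.3
    seed: int = 0
    scenario_levels: tuple = SCENARIO_LEVELS
    techniques: tuple = TECHNIQUES

    def __post_init__(self) -> None:
        if self.grid_size < 16:
            raise ConfigurationError(f"grid_size must be >= 16, got {self.grid_size}")
        if not self.cell_size > 0:
            raise ConfigurationError(f"cell_size must be > 0, got {self.cell_size}")
        for sp, p in self.base_prevalence.items():
            if not 0.0 < p < 1.0:
                raise ConfigurationError(f"base_prevalence[{sp}]={p} not in (0,1)")
        if self.secchi_response.get("perch", 1.0) <= 0:
            raise ConfigurationError("perch secchi_response must be positive")
        if self.secchi_response.get("pikeperch", -1.0) >= 0:
            raise ConfigurationError("pikeperch secchi_response must be negative")
        if self.technique_noise < 0:
            raise ConfigurationError("technique_noise must be >= 0")


def _subseed(seed: int, *labels) -> int:
    """Stable per-label child seed (< 2**31) from the master seed."""
    key = "|".join([str(seed), *map(str, labels)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def _gaussian_field(shape, range_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Smoothed, standardized white noise: a cheap stationary GRF."""
    z = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(z, sigma=max(range_cells, 1e-6), mode="reflect")
    return (f - f.mean()) / f.std()


def generate_landscape(config: HabitatGenConfig) -> Landscape:
    """Build a coastal landscape: mainland margin on the west edge, a few
    islands, depth increasing with distance from land, smooth Secchi field.

    Deterministic for a fixed ``config.seed``.
    """
    n = config.grid_size
    rng = np.random.default_rng(_subseed(config.seed, "landscape"))

    # Mainland: column width per row from a smoothed random profile.
    profile = ndimage.gaussian_filter1d(rng.standard_normal(n), sigma=n / 8)
    profile = (profile - profile.min()) / max(np.ptp(profile), 1e-12)
    widths = np.clip((0.08 + 0.12 * profile) * n, 1, int(0.3 * n)).astype(int)
    water = np.ones((n, n), dtype=bool)
    for r in range(n):
        water[r, : widths[r]] = False

    # A few small elliptical islands away from the margin.
    n_islands = rng.integers(2, 5)
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    for _ in range(n_islands):
        cr = rng.uniform(0.15 * n, 0.9 * n)
        cc = rng.uniform(0.45 * n, 0.9 * n)
        a = rng.uniform(0.02, 0.05) * n
        b = rng.uniform(0.02, 0.05) * n
        water &= ((ii - cr) / a) ** 2 + ((jj - cc) / b) ** 2 > 1.0

    frac = water.mean()
    if not 0.5 <= frac <= 0.95:  # widths are clipped so this cannot trip
        raise ConfigurationError(f"water fraction {frac:.2f} outside [0.5, 0.95]")

    # Depth grows with distance from land, plus smooth local relief.
    dist = ndimage.distance_transform_edt(water) * config.cell_size
    relief = _gaussian_field((n, n), n / 16, rng)
    depth = 2.0 + 18.0 * dist / dist.max() + 1.0 * relief
    depth = np.clip(depth, 0.5, None)
    depth = np.where(water, depth, np.nan)

    secchi = 5.0 + 1.0 * _gaussian_field((n, n), n / 8, rng)
    secchi = np.where(water, np.clip(secchi, 0.5, None), np.nan)

    cs = config.cell_size
    return Landscape(
        water_mask=RasterGrid(water.astype(float), cs, {"layer": "water_mask"}),
        depth=RasterGrid(depth, cs, {"layer": "depth", "units": "m"}),
        secchi_base=RasterGrid(secchi, cs, {"layer": "secchi", "units": "m"}),
    )


def scenario_prevalence(base: float, response: float, secchi_change_pct: float) -> float:
    """Target habitat prevalence under a scenario: logistic in log-odds."""
    return float(special.expit(special.logit(base) + response * secchi_change_pct / 100.0))


def generate_habitat_map(
    landscape: Landscape,
    species: str,
    scenario: float,
    technique: str,
    config: HabitatGenConfig,
) -> RasterGrid:
    """Binary recruitment-habitat raster for one (species, scenario, technique).

    Habitat cells (value 1.0) are the lowest-quantile cells of the
    species' latent field plus technique noise; land is NaN. Realized
    prevalence over water equals the logistic scenario target up to the
    cell-count rounding of the quantile.
    """
    if species not in config.base_prevalence:
        raise ConfigurationError(f"unknown species {species!r}")
    if technique not in config.techniques:
        raise ConfigurationError(f"unknown technique {technique!r}")
    if scenario not in config.scenario_levels:
        raise ConfigurationError(
            f"scenario {scenario!r} not among configured levels {config.scenario_levels}"
        )

    n = config.grid_size
    range_cells = config.autocorrelation_range / config.cell_size
    latent = _gaussian_field(
        (n, n), range_cells, np.random.default_rng(_subseed(config.seed, species, "latent"))
    )
    if config.technique_noise > 0:
        tech = _gaussian_field(
            (n, n),
            range_cells,
            np.random.default_rng(_subseed(config.seed, species, technique, "tech")),
        )
        latent = latent + config.technique_noise * tech

    p = scenario_prevalence(
        config.base_prevalence[species], config.secchi_response[species], scenario
    )
    water = landscape.water
    cutoff = np.quantile(latent[water], p)
    habitat = np.where(water, (latent <= cutoff).astype(float), np.nan)
    return RasterGrid(
        habitat,
        config.cell_size,
        {"species": species, "scenario": scenario, "technique": technique},
    )


def generate_monitoring(
    cpue_map: RasterGrid,
    n_sites: int,
    noise_sd: float,
    seed: int,
    slope: float = 1.0,
    intercept: float = 0.0,
) -> pd.DataFrame:
    """Sample monitoring sites and their observed CPUE from a CPUE map.

    Observed CPUE is ``slope · predicted + intercept`` plus Gaussian
    noise, truncated at zero (a gill net cannot catch negative fish).
    The defaults make observation an unbiased noisy copy of the map;
    slope/intercept support calibration-recovery simulations.

    Returns a table with columns ``site_id, row, col, observed_cpue``.
    """
    if n_sites < 3:
        raise ConfigurationError(f"n_sites must be >= 3, got {n_sites}")
    valid = np.argwhere(cpue_map.mask)
    if n_sites > len(valid):
        raise ConfigurationError(
            f"n_sites={n_sites} exceeds the {len(valid)} valid water cells"
        )
    rng = np.random.default_rng(seed)
    picks = valid[rng.choice(len(valid), size=n_sites, replace=False)]
    pred = cpue_map.values[picks[:, 0], picks[:, 1]]
    obs = slope * pred + intercept + rng.normal(0.0, noise_sd, size=n_sites)
    obs = np.maximum(obs, 0.0)
    return pd.DataFrame(
        {
            "site_id": [f"site_{i:03d}" for i in range(n_sites)],
            "row": picks[:, 0],
            "col": picks[:, 1],
            "observed_cpue": obs,
        }
    )
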