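"""Habitat productivity functions: availability → adult CPUE → biomass.

The habitat productivity function (HPF) is an empirical log-linear
relation between habitat availability ``x`` (proportion of water within
the migration radius that is recruitment habitat) and the expected
catch per unit effort of adult fish in a standardized gill net:

    CPUE = a · ln(x + c) + b

with species-specific coefficients fitted to tagging/monitoring data —
for perch (> 20 cm) a = 2.03 (± 0.69 SE), b = 9.39 (± 1.27 SE), c = 0,
and for pikeperch (> 30 cm) a = 0.05 (± 0.02 SE), b = 0.21 (± 0.04 SE),
c = 0.02. With c = 0 the perch curve diverges to −∞ as x → 0; predicted
CPUE is clamped at zero, which activates exactly below
x = exp(−b/a) ≈ 0.0098.

CPUE converts to biomass density (kg ha⁻¹) by a per-species linear
factor calibrated so the study-area mean CPUE maps to the study-area
mean biomass (perch 9.4/5.4, pikeperch 0.65/0.16 kg ha⁻¹ per CPUE
unit). Perch is a shallow-water species: its maps are limited to
water of at most 10 m depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import RasterGrid


@dataclass
class ProductivityFunction:
    """Log-linear CPUE model ``a·ln(x + c) + b`` with fit statistics."""

    slope: float
    intercept: float
    offset: float = 0.0
    slope_se: float | None = None
    intercept_se: float | None = None
    n: int | None = None
    p: float | None = None
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError(f"offset must be >= 0, got {self.offset}")

    @property
    def clamp_threshold(self) -> float:
        """Availability below which raw CPUE would be negative."""
        x = float(np.exp(-self.intercept / self.slope) - self.offset)
        return max(x, 0.0)


@dataclass
class SpeciesParams:
    """Per-species constants of the biomass chain.

    ``biomass_factor`` is kg ha⁻¹ of fish above the length cutoff per
    CPUE unit; ``length_proportion`` is the share of that biomass among
    all fish > 10 cm, used to expand predictions for comparison with
    whole-population estimates. ``depth_limit`` of None means the
    species is not depth-restricted.
    """

    name: str
    migration_distance: float
    length_cutoff_cm: float
    mean_weight_kg: float
    hpf: ProductivityFunction
    biomass_factor: float
    depth_limit: float | None = None
    length_proportion: float | None = None

    def __post_init__(self) -> None:
        for label, v in [
            ("migration_distance", self.migration_distance),
            ("length_cutoff_cm", self.length_cutoff_cm),
            ("mean_weight_kg", self.mean_weight_kg),
        ]:
            if not v > 0:
                raise ValueError(f"{label} must be > 0, got {v}")
        if not self.biomass_factor > 0:
            raise ValueError(f"biomass_factor must be > 0, got {self.biomass_factor}")
        if self.length_proportion is not None and not 0 < self.length_proportion <= 1:
            raise ValueError(
                f"length_proportion must be in (0, 1], got {self.length_proportion}"
            )


def default_species_params() -> dict[str, SpeciesParams]:
    """The published parameterization for perch and pikeperch."""
    perch_hpf = ProductivityFunction(
        slope=2.03, intercept=9.39, offset=0.0,
        slope_se=0.69, intercept_se=1.27, n=12, p=0.015, r2=0.46,
    )
    pike_hpf = ProductivityFunction(
        slope=0.05, intercept=0.21, offset=0.02,
        slope_se=0.02, intercept_se=0.04, n=12, p=0.013, r2=0.48,
    )
    return {
        "perch": SpeciesParams(
            name="perch",
            migration_distance=10_000.0,
            length_cutoff_cm=20.0,
            mean_weight_kg=0.23,
            hpf=perch_hpf,
            biomass_factor=9.4 / 5.4,
            depth_limit=10.0,
            length_proportion=9.4 / 16.0,
        ),
        "pikeperch": SpeciesParams(
            name="pikeperch",
            migration_distance=15_000.0,
            length_cutoff_cm=30.0,
            mean_weight_kg=0.51,
            hpf=pike_hpf,
            biomass_factor=0.65 / 0.16,
            depth_limit=None,
            length_proportion=0.65 / 1.5,
        ),
    }


def hpf_cpue(x, f: ProductivityFunction):
    """Evaluate the HPF at availability ``x`` (scalar or array).

    Returns max(0, a·ln(x + c) + b); monotone non-decreasing on [0, 1].
    NaN inputs (nodata cells) stay NaN. Raises if any finite x lies
    outside [0, 1].
    """
    arr = np.asarray(x, dtype=np.float64)
    finite = np.isfinite(arr)
    if np.any((arr[finite] < 0) | (arr[finite] > 1)):
        raise ValueError("availability x must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        raw = f.slope * np.log(arr + f.offset) + f.intercept
    out = np.where(finite, np.maximum(raw, 0.0), np.nan)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def cpue_map(availability: RasterGrid, f: ProductivityFunction) -> RasterGrid:
    """Apply the HPF cellwise to an availability grid."""
    values = hpf_cpue(availability.values, f)
    meta = dict(availability.meta)
    meta["units"] = "fish net-1 night-1"
    return RasterGrid(values, availability.cell_size, meta)


def cpue_to_biomass(cpue, sp: SpeciesParams):
    """Linear CPUE → biomass density conversion (kg ha⁻¹); 0 maps to 0."""
    arr = np.asarray(cpue, dtype=np.float64)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("CPUE must be non-negative")
    out = sp.biomass_factor * arr
    return float(out) if np.isscalar(cpue) or arr.ndim == 0 else out


def biomass_map(cpue: RasterGrid, sp: SpeciesParams) -> RasterGrid:
    """Cellwise CPUE → biomass conversion of a raster."""
    values = cpue_to_biomass(cpue.values, sp)
    meta = dict(cpue.meta)
    meta["units"] = "kg ha-1"
    return RasterGrid(values, cpue.cell_size, meta)


def length_class_expand(biomass_gt_cutoff, p: float):
    """Expand biomass above the length cutoff to biomass of fish > 10 cm.

    ``p`` is the proportion of >cutoff biomass among >10 cm biomass,
    from monitoring length-frequency distributions.
    """
    if not 0 < p <= 1:
        raise ValueError(f"length proportion must be in (0, 1], got {p}")
    arr = np.asarray(biomass_gt_cutoff, dtype=np.float64) / p
    return float(arr) if np.isscalar(biomass_gt_cutoff) or arr.ndim == 0 else arr


def apply_depth_mask(grid: RasterGrid, depth: RasterGrid, sp: SpeciesParams) -> RasterGrid:
    """Blank cells deeper than the species' depth limit (NaN); pass-through
    for species without a limit."""
    if sp.depth_limit is None:
        return grid.copy()
    grid.require_congruent(depth, "depth")
    values = np.where(
        np.nan_to_num(depth.values, nan=np.inf) > sp.depth_limit, np.nan, grid.values
    )
    out = RasterGrid(values, grid.cell_size, dict(grid.meta))
    out.meta["depth_limit_m"] = sp.depth_limit
    return out
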