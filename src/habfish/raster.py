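"""Raster container and single-band TIFF I/O.

All maps in the pipeline — land/water masks, depth, binary habitat,
availability, CPUE and biomass — travel as :class:`RasterGrid`: a 2D
float array on a square grid in projected metres, with NaN marking
nodata cells. Grid metadata (cell size, optional free-form attributes)
round-trips through the TIFF ImageDescription tag as JSON, so a written
file is self-describing without an external world file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


class RasterError(ValueError):
    """Shape, cell-size or mask inconsistency between rasters."""


@dataclass
class RasterGrid:
    """A rectangular grid of cell values in a projected coordinate system.

    Parameters
    ----------
    values :
        2D float array. NaN encodes nodata (land, outside study area).
    cell_size :
        Cell edge length in metres; cells are square.
    meta :
        Optional free-form metadata (species, scenario, units ...),
        preserved through TIFF round trips.
    """

    values: np.ndarray
    cell_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise RasterError(f"values must be 2D, got ndim={self.values.ndim}")
        if not self.cell_size > 0:
            raise RasterError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return ~np.isnan(self.values)

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares."""
        return self.cell_size**2 / 10_000.0

    def congruent_with(self, other: "RasterGrid") -> bool:
        return self.shape == other.shape and self.cell_size == other.cell_size

    def require_congruent(self, other: "RasterGrid", what: str = "raster") -> None:
        if not self.congruent_with(other):
            raise RasterError(
                f"{what}: shape/cell_size mismatch "
                f"({self.shape}@{self.cell_size} vs {other.shape}@{other.cell_size})"
            )

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.values.copy(), self.cell_size, dict(self.meta))


def write_raster(path: str | Path, grid: RasterGrid) -> Path:
    """Write a single-band float64 TIFF with JSON metadata tag.

    NaN cells are written as NaN and read back as nodata; cell size and
    ``meta`` are stored in the ImageDescription tag. Values round-trip
    bit-exactly (the band stays float64 on disk).
    """
    path = Path(path)
    desc = json.dumps({"cell_size": grid.cell_size, "nodata": "nan", "meta": grid.meta})
    tifffile.imwrite(path, grid.values, description=desc)
    return path


def read_raster(path: str | Path) -> RasterGrid:
    """Read a raster written by :func:`write_raster`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(np.float64)
        desc = page.tags.get("ImageDescription")
        if desc is None:
            raise RasterError(f"{path}: missing ImageDescription metadata tag")
        info = json.loads(desc.value)
    return RasterGrid(values, float(info["cell_size"]), dict(info.get("meta", {})))
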