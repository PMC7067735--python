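"""Habitat availability by circular focal statistics.

For every water cell, availability ``x`` is the proportion of the water
area within the species' migration radius that is predicted recruitment
habitat: habitat cells in the window divided by water cells in the
window. Land cells and cells beyond the grid edge are excluded from
both the numerator and the denominator, so ``x`` stays an unbiased
proportion of observable water. Distance is centre-to-centre Euclidean
in projected metres; migration barriers (land between cells) are
deliberately ignored — the window is a plain disc.

The fast path is FFT convolution of 0/1 indicator arrays with the disc
kernel. Counts are integers, so convolution results are rounded to the
nearest integer before dividing; the result is therefore exactly the
ratio a brute-force double loop would produce.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .raster import RasterError, RasterGrid


def circular_kernel(radius: float, cell_size: float) -> np.ndarray:
    """Boolean disc: cell (i, j) included iff centre-to-centre distance
    from the kernel centre is <= radius.

    ``radius < cell_size`` is rejected: the window would degenerate to
    the centre cell alone and availability would just echo the habitat
    map.
    """
    if radius < cell_size:
        raise ValueError(
            f"radius ({radius} m) must be >= cell_size ({cell_size} m)"
        )
    r_cells = int(np.floor(radius / cell_size))
    offsets = np.arange(-r_cells, r_cells + 1)
    di, dj = np.meshgrid(offsets, offsets, indexing="ij")
    return (np.hypot(di, dj) * cell_size) <= radius


def habitat_availability(
    habitat: RasterGrid, water_mask: RasterGrid, radius: float
) -> RasterGrid:
    """Availability grid for one habitat map.

    Returns values in [0, 1] on water cells and NaN on land. Habitat
    must be binary over water (1 habitat / 0 not), NaN on land, and a
    subset of water.
    """
    habitat.require_congruent(water_mask, "habitat vs water_mask")
    water = water_mask.values == 1.0
    hab = np.nan_to_num(habitat.values, nan=0.0) > 0.5
    if np.any(hab & ~water):
        raise RasterError("habitat cells found outside the water mask")

    kernel = circular_kernel(radius, habitat.cell_size).astype(np.float64)
    num = signal.fftconvolve(hab.astype(np.float64), kernel, mode="same")
    den = signal.fftconvolve(water.astype(np.float64), kernel, mode="same")
    # Counts are integers; round away FFT noise so ratios are exact.
    num = np.rint(num)
    den = np.rint(den)

    x = np.full(habitat.shape, np.nan)
    # Centre cell is in-kernel and water, so den >= 1 wherever we divide.
    x[water] = num[water] / den[water]
    meta = dict(habitat.meta)
    meta["radius_m"] = radius
    return RasterGrid(x, habitat.cell_size, meta)


def habitat_availability_bruteforce(
    habitat: RasterGrid, water_mask: RasterGrid, radius: float
) -> RasterGrid:
    """Reference double-loop implementation; O(cells × kernel).

    Used as the exactness oracle for :func:`habitat_availability`.
    """
    habitat.require_congruent(water_mask, "habitat vs water_mask")
    water = water_mask.values == 1.0
    hab = np.nan_to_num(habitat.values, nan=0.0) > 0.5
    kernel = circular_kernel(radius, habitat.cell_size)
    r = kernel.shape[0] // 2
    nrow, ncol = habitat.shape
    x = np.full(habitat.shape, np.nan)
    for i in range(nrow):
        for j in range(ncol):
            if not water[i, j]:
                continue
            # clip the window to the grid; clip the kernel to match
            i0, i1 = max(i - r, 0), min(i + r + 1, nrow)
            j0, j1 = max(j - r, 0), min(j + r + 1, ncol)
            kwin = kernel[i0 - (i - r) : i1 - (i - r), j0 - (j - r) : j1 - (j - r)]
            wwin = water[i0:i1, j0:j1] & kwin
            n_wat = int(wwin.sum())
            n_hab = int((hab[i0:i1, j0:j1] & wwin).sum())
            x[i, j] = n_hab / n_wat
    meta = dict(habitat.meta)
    meta["radius_m"] = radius
    return RasterGrid(x, habitat.cell_size, meta)
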