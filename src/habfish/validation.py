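"""Validation of predicted CPUE against gill-net monitoring catches.

Predicted CPUE at each monitoring site is looked up from the CPUE map
and regressed as ``observed = a · predicted + b`` by ordinary least
squares — observed on predicted, no errors-in-variables correction.
Sites falling on nodata cells (land, or beyond a species' depth limit)
are dropped with a warning; site exclusions (e.g. a fishing-ban area)
are a config-level site list filter, never hard-coded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .raster import RasterGrid

logger = logging.getLogger(__name__)


@dataclass
class ValidationFit:
    """OLS fit of observed on predicted CPUE."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r2: float
    f_stat: float
    df: tuple[int, int]
    p: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "slope_se": self.slope_se,
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "r2": self.r2,
            "f_stat": self.f_stat,
            "df": list(self.df),
            "p": self.p,
            "n": self.n,
        }


def extract_predictions(
    cpue_map: RasterGrid, sites: pd.DataFrame, exclude_sites: list[str] | None = None
) -> pd.DataFrame:
    """Pair each monitoring site with the predicted CPUE at its cell.

    ``sites`` must have columns ``site_id, row, col, observed_cpue``.
    Sites named in ``exclude_sites`` are filtered first; sites on nodata
    cells are dropped with a logged warning. Errors if no site remains.
    """
    df = sites.copy()
    if exclude_sites:
        df = df[~df["site_id"].isin(exclude_sites)]
    rows = df["row"].to_numpy(dtype=int)
    cols = df["col"].to_numpy(dtype=int)
    nrow, ncol = cpue_map.shape
    if np.any((rows < 0) | (rows >= nrow) | (cols < 0) | (cols >= ncol)):
        raise ValueError("monitoring site outside the raster extent")
    pred = cpue_map.values[rows, cols]
    on_nodata = np.isnan(pred)
    if on_nodata.any():
        dropped = df.loc[on_nodata, "site_id"].tolist()
        logger.warning("dropping %d site(s) on nodata cells: %s", len(dropped), dropped)
    out = df.loc[~on_nodata, ["site_id", "observed_cpue"]].copy()
    out["predicted_cpue"] = pred[~on_nodata]
    if out.empty:
        raise ValueError("all monitoring sites fall on nodata cells")
    return out.reset_index(drop=True)


def fit_obs_vs_pred(pairs: pd.DataFrame) -> ValidationFit:
    """OLS of observed on predicted CPUE with standard fit statistics.

    Requires >= 3 pairs and non-degenerate predicted values.
    """
    y = pairs["observed_cpue"].to_numpy(dtype=float)
    x = pairs["predicted_cpue"].to_numpy(dtype=float)
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need >= 3 site pairs, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("predicted CPUE is constant; regression is degenerate")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    if np.ptp(y) == 0:
        # observed values constant: slope 0 explains nothing, by convention
        r2, f_stat, p = 0.0, 0.0, 1.0
    else:
        r2, f_stat, p = float(model.rsquared), float(model.fvalue), float(model.f_pvalue)
    return ValidationFit(
        slope=float(model.params[1]),
        slope_se=float(model.bse[1]),
        intercept=float(model.params[0]),
        intercept_se=float(model.bse[0]),
        r2=r2,
        f_stat=f_stat,
        df=(int(model.df_model), int(model.df_resid)),
        p=p,
        n=n,
    )
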