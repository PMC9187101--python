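"""Single ecosystem functions and the averaging multifunctionality index.

Four plot-level functions are derived from soil measurements and community
traits:

* nutrient cycling — composite of total P, total N, available P and
  ammonium N (z-scored before averaging, because their units differ);
* carbon stocks  — soil organic carbon (SOC);
* water regulation — soil water content (SWC);
* wood production — community-weighted mean plant height.

Each function column is standardized to mean 0 / SD 1 across plots (sample
SD), and multifunctionality is their per-plot arithmetic mean:
MF = (1/n_functions) Σ f_i with n_functions = 4.  MF therefore has mean 0
across plots and SD at most 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SOIL_VARIABLES",
    "NUTRIENT_CONSTITUENTS",
    "FUNCTION_COLUMNS",
    "ZeroVarianceError",
    "zscore",
    "aggregate_layers",
    "ensure_cn",
    "single_functions",
    "multifunctionality",
    "function_matrix",
]

SOIL_VARIABLES = ("SWC", "SSC", "SOC", "TP", "AP", "TN", "AN", "pH")
NUTRIENT_CONSTITUENTS = ("TP", "TN", "AP", "AN")
FUNCTION_COLUMNS = ("nutrient_cycling", "carbon_stocks", "water_regulation", "wood_production")


class ZeroVarianceError(ValueError):
    def __init__(self, indicator: str):
        super().__init__(f"indicator '{indicator}' has zero variance; cannot standardize")
        self.indicator = indicator


def zscore(values, name: str = "indicator", ddof: int = 1) -> np.ndarray:
    """(x − mean)/SD with the sample SD; errors on constant input."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("zscore needs at least 2 plots")
    if np.any(~np.isfinite(x)):
        raise ValueError(f"indicator '{name}' has non-finite values")
    sd = x.std(ddof=ddof)
    if sd <= 0:
        raise ZeroVarianceError(name)
    return (x - x.mean()) / sd


def aggregate_layers(soil: pd.DataFrame, mode: str = "mean") -> pd.DataFrame:
    """Collapse per-depth-layer soil records to one row per plot.

    ``mode='mean'`` takes the unweighted mean over layers; ``mode='first'``
    keeps the shallowest layer only.  A table without a ``layer`` column is
    returned unchanged.
    """
    if "layer" not in soil.columns:
        return soil
    value_cols = [c for c in soil.columns if c != "layer"]
    if mode == "mean":
        return soil.groupby(level=0)[value_cols].mean()
    if mode == "first":
        order = soil.sort_values("layer").groupby(level=0).head(1)
        return order[value_cols].sort_index()
    raise ValueError(f"unknown layer aggregation mode {mode!r}")


def ensure_cn(soil: pd.DataFrame) -> pd.DataFrame:
    """Add the soil C:N ratio (SOC/TN) when not supplied directly."""
    if "CN" in soil.columns:
        return soil
    out = soil.copy()
    if np.any(out["TN"].to_numpy(dtype=float) <= 0):
        raise ValueError("TN must be positive to derive the C:N ratio")
    out["CN"] = out["SOC"] / out["TN"]
    return out


def _require(soil: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in soil.columns]
    if missing:
        raise ValueError(f"soil table is missing columns: {', '.join(missing)}")
    bad = soil[list(cols)].isna().any(axis=1)
    if bad.any():
        plots = ", ".join(map(str, soil.index[bad]))
        raise ValueError(f"incomplete soil records for plot(s): {plots}")


def single_functions(soil: pd.DataFrame, cwm_height: pd.Series,
                     nutrient_mode: str = "zscore") -> pd.DataFrame:
    """The four standardized single-function columns (no MF yet).

    ``nutrient_mode='zscore'`` (default) z-scores TP/TN/AP/AN before
    averaging them into the nutrient-cycling composite; ``'raw'`` averages
    the raw values (sensitivity-analysis mode — the constituents' units
    differ, so the default is the standardized composite).  All four columns
    are re-standardized so each has mean 0 and sample SD 1.
    """
    _require(soil, NUTRIENT_CONSTITUENTS + ("SOC", "SWC"))
    heights = cwm_height.reindex(soil.index)
    if heights.isna().any():
        plots = ", ".join(map(str, soil.index[heights.isna()]))
        raise ValueError(f"missing CWM height for plot(s): {plots}")
    if nutrient_mode == "zscore":
        nutrient_raw = np.mean(
            [zscore(soil[c].to_numpy(), name=c) for c in NUTRIENT_CONSTITUENTS], axis=0
        )
    elif nutrient_mode == "raw":
        nutrient_raw = soil[list(NUTRIENT_CONSTITUENTS)].mean(axis=1).to_numpy()
    else:
        raise ValueError(f"unknown nutrient_mode {nutrient_mode!r}")
    out = pd.DataFrame(
        {
            "nutrient_cycling": zscore(nutrient_raw, name="nutrient_cycling"),
            "carbon_stocks": zscore(soil["SOC"].to_numpy(), name="SOC"),
            "water_regulation": zscore(soil["SWC"].to_numpy(), name="SWC"),
            "wood_production": zscore(heights.to_numpy(), name="cwm_height"),
        },
        index=soil.index,
    )
    out.index.name = soil.index.name or "plot"
    return out


def multifunctionality(fm: pd.DataFrame) -> pd.Series:
    """Averaging MF index: per-plot mean of the four standardized functions."""
    missing = [c for c in FUNCTION_COLUMNS if c not in fm.columns]
    if missing:
        raise ValueError(f"function matrix is missing columns: {', '.join(missing)}")
    mf = fm[list(FUNCTION_COLUMNS)].mean(axis=1)
    mf.name = "MF"
    return mf


def function_matrix(soil: pd.DataFrame, cwm_height: pd.Series,
                    nutrient_mode: str = "zscore") -> pd.DataFrame:
    """Convenience: single functions plus the MF column in one table."""
    fm = single_functions(soil, cwm_height, nutrient_mode=nutrient_mode)
    fm["MF"] = multifunctionality(fm)
    return fm
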