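"""Predicted-vs-observed comparison of wood-formation dynamics.

Pairs model predictions with microcore-derived observations (season
boundaries, per-cell timings, cell growth rates), summarizes agreement
with OLS regression and Pearson correlation, and provides LOESS pattern
curves for visual comparison of intra-annual profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import DataError

__all__ = ["compare", "loess_pattern", "season_summary", "RegressionSummary"]


@dataclass
class RegressionSummary:
    """OLS fit of observed on predicted, with the reverse direction too.

    ``mean_bias = mean(predicted - observed)``: positive values mean the
    model runs late relative to the observations.
    """

    variable: str
    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    p_value: float
    n: int
    mean_bias: float
    slope_pred_on_obs: float
    intercept_pred_on_obs: float
    degenerate: bool = False


def _maybe_transform(x: np.ndarray, transform: str | None) -> np.ndarray:
    if transform is None:
        return x
    if transform == "log":
        if (x <= 0).any():
            raise DataError("log transform requires positive values")
        return np.log(x)
    if transform == "rank":
        return stats.rankdata(x)
    raise ValueError(f"unknown transform {transform!r}")


def compare(
    predicted: np.ndarray,
    observed: np.ndarray,
    variable: str = "value",
    transform: str | None = None,
) -> tuple[pd.DataFrame, RegressionSummary]:
    """Pair predictions with observations and regress observed on predicted.

    Rows with a missing member are dropped (pairs only, no imputation).
    An optional log or rank transform is applied to both members before
    the regression.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise DataError("predicted and observed must have equal length")
    ok = np.isfinite(pred) & np.isfinite(obs)
    pred, obs = pred[ok], obs[ok]
    if pred.size < 3:
        raise DataError(f"need >= 3 pairs, got {pred.size}")
    table = pd.DataFrame(
        {"variable": variable, "predicted": pred, "observed": obs}
    )
    x = _maybe_transform(pred, transform)
    y = _maybe_transform(obs, transform)
    mean_bias = float(np.mean(pred - obs))
    if np.std(x) == 0 or np.std(y) == 0:
        summary = RegressionSummary(
            variable, np.nan, np.nan, np.nan, np.nan, np.nan,
            int(pred.size), mean_bias, np.nan, np.nan, degenerate=True,
        )
        return table, summary
    fit = stats.linregress(x, y)
    rev = stats.linregress(y, x)
    summary = RegressionSummary(
        variable=variable,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=int(pred.size),
        mean_bias=mean_bias,
        slope_pred_on_obs=float(rev.slope),
        intercept_pred_on_obs=float(rev.intercept),
    )
    return table, summary


def loess_pattern(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.7,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Locally weighted (LOESS) pattern curve, default span 0.7.

    Returns ``(grid, fitted)``; the grid defaults to the sorted unique x.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must be in (0, 1], got {span}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise DataError(f"need >= 10 points for a LOESS pattern, got {x.size}")
    if grid is None:
        grid = np.unique(x)
    fitted = lowess(y, x, frac=span, xvals=np.asarray(grid, dtype=float))
    return np.asarray(grid, dtype=float), fitted


def season_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-site mean +/- SD of observed and predicted season boundaries.

    ``records`` is tidy with columns ``site_id, year, source`` (one of
    ``observed``/``predicted``) and ``start_doy, end_doy``.  Output has one
    row per site with ``{start,end}_{observed,predicted}_{mean,sd}``
    columns plus formatted ``"mean +/- sd"`` strings, mirroring the usual
    wood-phenology summary table.
    """
    required = {"site_id", "year", "source", "start_doy", "end_doy"}
    missing = required - set(records.columns)
    if missing:
        raise DataError(f"season records missing columns: {sorted(missing)}")
    counts = records.groupby(["site_id", "source"])["year"].nunique()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise DataError(f"need >= 2 years per site and source, short: {bad}")
    rows = []
    for site, grp in records.groupby("site_id"):
        row: dict = {"site_id": site}
        for var in ("start_doy", "end_doy"):
            for source in ("observed", "predicted"):
                vals = grp.loc[grp["source"] == source, var].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                mean = float(np.mean(vals)) if vals.size else np.nan
                sd = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
                key = f"{var.removesuffix('_doy')}_{source}"
                row[f"{key}_mean"] = mean
                row[f"{key}_sd"] = sd
                row[key] = f"{mean:.0f} ± {sd:.1f}" if vals.size else "-"
        rows.append(row)
    return pd.DataFrame(rows)
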