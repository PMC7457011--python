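"""Per-cell division and enlargement timings from the daily growth curve.

The seasonal integral of the daily growth rate is split into ``n_cells``
equal quanta.  A new cambial cell starts dividing only once its
predecessor has left the cambial zone, so cell *i* enlarges on the first
day the cumulative growth reaches ``i`` quanta, and starts dividing the
day its predecessor enlarged (cell 1 divides on the season's first day).
The cambial cell growth rate assigned to each cell is the mean daily
growth rate over its cambial residence window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DataError, GrowthSeries

__all__ = ["extract_cell_timings", "cambial_cell_growth_rate"]


def _season_arrays(growth: GrowthSeries, year: int) -> tuple[np.ndarray, np.ndarray]:
    start, end = growth.season(year)
    if np.isnan(start):
        raise DataError(f"year {year} has a zero-length growing season")
    yr = growth.year(year)
    mask = (yr["doy"] >= start) & (yr["doy"] <= end)
    doys = yr.loc[mask, "doy"].to_numpy(dtype=int)
    gr = yr.loc[mask, "gr"].to_numpy(dtype=float)
    if gr.sum() <= 0:
        raise DataError(f"year {year} has zero total growth")
    return doys, gr


def extract_cell_timings(
    growth: GrowthSeries,
    year: int,
    n_cells: int,
    rate_mode: str = "window_mean",
) -> pd.DataFrame:
    """Predict per-cell timings for one year.

    Parameters
    ----------
    growth : GrowthSeries
        Simulation output containing ``year``.
    year : int
        Calendar year to process.
    n_cells : int
        Observed annual cell production (>= 1).
    rate_mode : {"window_mean", "quantum"}
        How the cambial cell growth rate is computed: the mean Gr over the
        cell's cambial residence window (default), or the growth quantum
        ``sum(Gr)/n_cells`` itself, identical for every cell.

    Returns
    -------
    DataFrame with columns ``cell_position, division_doy, enlargement_doy,
    cambial_rate``.  Several cells may share an enlargement day when the
    daily growth increment spans more than one quantum.
    """
    if n_cells < 1:
        raise DataError(f"n_cells must be >= 1, got {n_cells}")
    doys, gr = _season_arrays(growth, year)
    cum = np.cumsum(gr)
    total = cum[-1]
    q = total / n_cells
    thresholds = np.arange(1, n_cells + 1) * q
    # first season day with cumulative Gr >= i*q; guard the final threshold
    # against floating-point overshoot of the exact total
    idx = np.searchsorted(cum, thresholds, side="left")
    idx = np.minimum(idx, doys.shape[0] - 1)
    enlargement = doys[idx]
    division = np.empty(n_cells, dtype=int)
    division[0] = doys[0]
    division[1:] = enlargement[:-1]
    out = pd.DataFrame(
        {
            "cell_position": np.arange(1, n_cells + 1),
            "division_doy": division,
            "enlargement_doy": enlargement,
        }
    )
    out["cambial_rate"] = cambial_cell_growth_rate(growth, year, out, rate_mode)
    return out


def cambial_cell_growth_rate(
    growth: GrowthSeries,
    year: int,
    timings: pd.DataFrame,
    rate_mode: str = "window_mean",
) -> np.ndarray:
    """Growth rate assigned to each cambial cell (nondimensional, [0, 1]).

    ``window_mean`` averages Gr over ``[division_doy, enlargement_doy]``
    inclusive — a cell occupies the cambium on both its first and last day
    there, so the window is never empty.
    """
    doys, gr = _season_arrays(growth, year)
    if rate_mode == "quantum":
        q = gr.sum() / len(timings)
        return np.full(len(timings), min(q, 1.0))
    if rate_mode != "window_mean":
        raise ValueError(f"unknown rate_mode {rate_mode!r}")
    doy_index = {d: i for i, d in enumerate(doys)}
    rates = np.empty(len(timings))
    for k, (d0, d1) in enumerate(
        zip(timings["division_doy"].to_numpy(), timings["enlargement_doy"].to_numpy())
    ):
        i0, i1 = doy_index[int(d0)], doy_index[int(d1)]
        rates[k] = gr[i0 : i1 + 1].mean()
    return rates
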