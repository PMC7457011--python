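"""Ring-width detrending and site chronology construction.

Raw ring widths carry an age/size trend.  Dendro practice divides each
tree's widths by a stiff cubic smoothing spline whose frequency response
is 0.50 at a wavelength equal to a stated fraction of the series length
(the "67% spline"), then averages the resulting dimensionless indices
across trees with a robust mean.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import DataError

__all__ = ["spline_detrend", "detrend_spline_curve", "build_chronology", "biweight_mean"]


def _spline_lambda(n: int, frequency_cutoff: float) -> float:
    """Penalty giving a 0.50 frequency response at wavelength cutoff*n.

    For the discrete second-difference smoother the transfer function at
    frequency f (cycles/year) is 1 / (1 + lam * (2 sin(pi f))^4); solving
    for 0.5 at f = 1/p gives lam = (2 sin(pi/p))^-4.
    """
    p = frequency_cutoff * n
    if p <= 2:
        raise DataError(f"cutoff wavelength {p:.2f} yr too short for a spline")
    return float((2.0 * np.sin(np.pi / p)) ** -4)


def detrend_spline_curve(
    widths: np.ndarray, frequency_cutoff: float = 0.67
) -> np.ndarray:
    """Fitted growth-trend curve for one tree's width series.

    Solves the penalized least-squares (Whittaker-type cubic smoothing
    spline) problem ``min ||y - g||^2 + lam ||D2 g||^2`` on the annual
    grid, with ``lam`` set by the frequency-response criterion.
    """
    y = np.asarray(widths, dtype=float)
    n = y.shape[0]
    if n < 8:
        raise DataError(f"need >= 8 years to detrend, got {n}")
    if (y <= 0).any():
        raise DataError("ring widths must be positive")
    lam = _spline_lambda(n, frequency_cutoff)
    d2 = np.diff(np.eye(n), n=2, axis=0)
    a = np.eye(n) + lam * d2.T @ d2
    return np.linalg.solve(a, y)


def spline_detrend(
    series: pd.Series,
    frequency_cutoff: float = 0.67,
    curve_floor: float | str | None = "auto",
) -> pd.Series:
    """Per-tree ring-width indices: width / fitted spline.

    ``series`` is indexed by contiguous years.  Indices are
    scale-invariant (multiplying the widths by a constant leaves them
    unchanged) and average close to 1 for well-behaved input.

    Series containing locally absent rings (near-zero widths recorded
    for no-growth years) can pull the fitted curve nonpositive.  By
    default (``curve_floor="auto"``) such curves are clipped to a small
    positive fraction of the median width with a warning, the standard
    pragmatic treatment; ``curve_floor=None`` raises instead.
    """
    years = series.index.to_numpy()
    if len(years) > 1 and not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
        raise DataError("ring-width years must be contiguous")
    y = series.to_numpy()
    curve = detrend_spline_curve(y, frequency_cutoff)
    if (curve <= 0).any():
        if curve_floor is None:
            raise DataError("degenerate detrending fit: nonpositive spline values")
        floor = 0.001 * float(np.median(y)) if curve_floor == "auto" else float(curve_floor)
        warnings.warn(
            f"detrending curve clipped to {floor:.4g} at "
            f"{int((curve <= 0).sum())} year(s) (locally absent rings?)"
        )
        curve = np.maximum(curve, floor)
    return pd.Series(y / curve, index=series.index, name="index")


def biweight_mean(x: np.ndarray, c: float = 9.0) -> float:
    """Tukey's biweight robust mean (location estimate)."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return np.nan
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return float(med)
    u = (x - med) / (c * mad)
    w = (1 - u**2) ** 2
    w[np.abs(u) >= 1] = 0.0
    if w.sum() == 0:
        return float(med)
    return float(np.sum(w * x) / np.sum(w))


def build_chronology(
    indices: dict[str, pd.Series],
    robust: bool = True,
) -> pd.DataFrame:
    """Average per-tree index series into a site chronology.

    Parameters
    ----------
    indices : dict of tree_id -> year-indexed index series
    robust : bool
        Tukey biweight mean across trees (default); arithmetic mean
        otherwise.

    Returns a DataFrame with columns ``year, index, n_trees``; years with
    no contributing tree are dropped with a warning.
    """
    if len(indices) < 2:
        raise DataError("need >= 2 trees to build a chronology")
    wide = pd.DataFrame(indices)
    years = np.arange(wide.index.min(), wide.index.max() + 1)
    missing = sorted(set(years) - set(wide.index))
    if missing:
        warnings.warn(f"years with no trees dropped: {missing}")
    agg = biweight_mean if robust else np.nanmean
    rows = []
    for year, row in wide.iterrows():
        vals = row.to_numpy(dtype=float)
        n = int(np.isfinite(vals).sum())
        if n == 0:
            warnings.warn(f"year {year} has no contributing trees; dropped")
            continue
        rows.append({"year": int(year), "index": float(agg(vals)), "n_trees": n})
    return pd.DataFrame(rows)
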