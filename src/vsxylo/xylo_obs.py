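"""Observed xylogenesis: from weekly cell counts to per-cell timings.

Microcore monitoring yields, on each sampling day, the number of cells in
the cambial, enlarging, wall-thickening and mature phases.  Smoothing the
counts to daily resolution and thresholding the cumulative production
curves gives the day of year on which each cell (by its position in the
radial file) entered each differentiation stage — the observational
counterpart of the model-derived timings.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .core import DataError

__all__ = [
    "PHASES",
    "smooth_counts",
    "smooth_all_phases",
    "extract_observed_timings",
    "wood_formation_window",
    "standardize_tracheidogram",
    "observed_cell_growth_rate",
]

PHASES = ("cambial", "enlarging", "wall", "mature")
_PHASE_COLS = {
    "cambial": "n_cambial",
    "enlarging": "n_enlarging",
    "wall": "n_wall",
    "mature": "n_mature",
}


def smooth_counts(
    records: pd.DataFrame,
    phase: str,
    lam: float | None = None,
    per_tree: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a penalized cubic spline to one phase's counts for a site-year.

    By default counts are pooled (averaged) across trees per sampling day
    before fitting; with ``per_tree=True`` each tree is smoothed
    separately and the fitted curves averaged.  The smoothing parameter
    defaults to generalized cross-validation.  Returns ``(doys, values)``
    on a daily grid spanning the sampling window, with negative fitted
    values clipped to zero.
    """
    if phase not in _PHASE_COLS:
        raise ValueError(f"phase must be one of {PHASES}, got {phase!r}")
    col = _PHASE_COLS[phase]
    if per_tree and records["tree_id"].nunique() > 1:
        curves = [
            smooth_counts(grp, phase, lam=lam)
            for _, grp in records.groupby("tree_id")
        ]
        grid = curves[0][0]
        if any(not np.array_equal(g, grid) for g, _ in curves[1:]):
            raise DataError("per-tree smoothing needs a shared sampling span")
        return grid, np.mean([v for _, v in curves], axis=0)
    pooled = records.groupby("doy")[col].mean()
    if len(pooled) < 5:
        site = records["site_id"].iloc[0] if "site_id" in records else "?"
        year = records["year"].iloc[0] if "year" in records else "?"
        raise DataError(
            f"site-year {site}/{year}: need >=5 sampling dates for {phase}, "
            f"got {len(pooled)}"
        )
    x = pooled.index.to_numpy(dtype=float)
    y = pooled.to_numpy(dtype=float)
    grid = np.arange(int(x.min()), int(x.max()) + 1, dtype=float)
    if np.allclose(y, y[0]):
        # constant data (incl. all-zero): the spline is the constant
        return grid, np.maximum(np.full_like(grid, y[0]), 0.0)
    spl = make_smoothing_spline(x, y, lam=lam)
    fitted = np.maximum(spl(grid), 0.0)
    return grid, fitted


def smooth_all_phases(
    records: pd.DataFrame, lam: float | None = None
) -> dict[str, np.ndarray]:
    """Smooth all four phases onto one shared daily grid.

    Returns a dict with key ``"doy"`` (the grid) plus one daily curve per
    phase name.
    """
    out: dict[str, np.ndarray] = {}
    grid = None
    for phase in PHASES:
        g, v = smooth_counts(records, phase, lam=lam)
        if grid is None:
            grid = g
        out[phase] = v
    out["doy"] = grid
    return out


def _cumulative_curves(curves: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Cumulative production curves, forced nondecreasing by running max."""
    p_e = curves["enlarging"] + curves["wall"] + curves["mature"]
    p_w = curves["wall"] + curves["mature"]
    p_m = curves["mature"]
    return {
        "P_E": np.maximum.accumulate(p_e),
        "P_W": np.maximum.accumulate(p_w),
        "P_M": np.maximum.accumulate(p_m),
    }


def _first_crossing(grid: np.ndarray, curve: np.ndarray, j: float) -> float:
    idx = np.nonzero(curve >= j)[0]
    return float(grid[idx[0]]) if idx.size else np.nan


def extract_observed_timings(
    curves: dict[str, np.ndarray],
    n_cells: int,
    continuity_correction: float = 0.5,
) -> pd.DataFrame:
    """Observed per-cell stage-entry days from smoothed phase curves.

    Cell ``j`` enters a stage on the first grid day its cumulative
    production curve reaches ``j - continuity_correction``.  The default
    half-cell correction accounts for integer counts sitting, on average,
    half a cell below the latent continuous production curve between cell
    entries; set it to 0 for the uncorrected ``>= j`` rule (exact on step
    curves either way).  Cells whose threshold is never reached get NaN
    timings and ``incomplete=True`` — they are flagged, never fabricated.

    Returns columns ``cell_position, t_enlarge, t_wall, t_mature,
    dur_enlarge, incomplete``.
    """
    if n_cells < 1:
        raise DataError(f"n_cells must be >= 1, got {n_cells}")
    cc = continuity_correction
    if not 0.0 <= cc < 1.0:
        raise ValueError(f"continuity_correction must be in [0, 1), got {cc}")
    grid = curves["doy"]
    cum = _cumulative_curves(curves)
    rows = []
    for j in range(1, n_cells + 1):
        te = _first_crossing(grid, cum["P_E"], j - cc)
        tw = _first_crossing(grid, cum["P_W"], j - cc)
        tm = _first_crossing(grid, cum["P_M"], j - cc)
        rows.append(
            {
                "cell_position": j,
                "t_enlarge": te,
                "t_wall": tw,
                "t_mature": tm,
                "dur_enlarge": tw - te,
                "incomplete": bool(np.isnan(te) or np.isnan(tw) or np.isnan(tm)),
            }
        )
    return pd.DataFrame(rows)


def wood_formation_window(
    curves: dict[str, np.ndarray],
    margin: float = 1.0,
    n_baseline_days: int = 3,
) -> tuple[float, float]:
    """Observed wood-formation window ``(start_doy, end_doy)``.

    Start: first day the smoothed cambial count exceeds its early-spring
    baseline (mean over the first ``n_baseline_days`` grid days) by
    ``margin`` cells.  End: maturation day of the last fully matured cell.
    A flat cambial curve leaves the start undefined (NaN, flagged by a
    warning).
    """
    grid = curves["doy"]
    cambial = curves["cambial"]
    baseline = float(np.mean(cambial[:n_baseline_days]))
    above = np.nonzero(cambial > baseline + margin)[0]
    if above.size == 0:
        warnings.warn("cambial curve never rises above baseline; start undefined")
        start = np.nan
    else:
        start = float(grid[above[0]])
    p_m = _cumulative_curves(curves)["P_M"]
    n_last = np.floor(p_m.max() + 1e-9)
    end = _first_crossing(grid, p_m, n_last) if n_last >= 1 else np.nan
    return start, end


def standardize_tracheidogram(
    files: list[np.ndarray],
    target_n: int,
    lam: float | None = 1e-4,
) -> np.ndarray:
    """Standardize radial-diameter profiles to a common cell number.

    Each radial file of ``n`` cells is placed at relative positions
    ``(j - 0.5)/n``, linearly resampled to ``target_n`` positions, then
    averaged across files with a light penalized-spline smooth over
    position.  Empty files are skipped with a warning.
    """
    if target_n < 2:
        raise DataError("target_n must be >= 2")
    pos_target = (np.arange(1, target_n + 1) - 0.5) / target_n
    resampled = []
    for arr in files:
        arr = np.asarray(arr, dtype=float)
        if arr.size == 0:
            warnings.warn("skipping empty tracheidogram file")
            continue
        if arr.size < 2:
            warnings.warn("skipping tracheidogram file with a single cell")
            continue
        if (arr <= 0).any():
            raise DataError("tracheidogram diameters must be positive")
        pos = (np.arange(1, arr.size + 1) - 0.5) / arr.size
        resampled.append(np.interp(pos_target, pos, arr))
    if not resampled:
        raise DataError("no usable tracheidogram files")
    mean_profile = np.mean(resampled, axis=0)
    if target_n >= 5 and lam is not None:
        spl = make_smoothing_spline(pos_target, mean_profile, lam=lam)
        mean_profile = np.maximum(spl(pos_target), 0.0)
    return mean_profile


def observed_cell_growth_rate(
    diameters: np.ndarray,
    dur_enlarge: np.ndarray,
) -> np.ndarray:
    """Scaled observed cell growth rate: diameter / enlargement duration,
    normalized by the site-year maximum to [0, 1].

    Cells with zero or missing duration are excluded (NaN in the output).
    """
    diameters = np.asarray(diameters, dtype=float)
    dur = np.asarray(dur_enlarge, dtype=float)
    if diameters.shape != dur.shape:
        raise DataError("diameters and durations must align by cell position")
    valid = np.isfinite(dur) & (dur > 0) & np.isfinite(diameters)
    if not valid.any():
        raise DataError("all enlargement durations are zero or missing")
    raw = np.full_like(diameters, np.nan)
    raw[valid] = diameters[valid] / dur[valid]
    return raw / np.nanmax(raw)
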