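"""Matplotlib views of the pipeline's main comparisons."""

from __future__ import annotations

import numpy as np

from .validation import loess_pattern

__all__ = [
    "plot_partial_rates",
    "plot_indices",
    "plot_pred_obs",
    "plot_timing_patterns",
]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_partial_rates(growth, year: int, ax=None):
    """Daily photoperiod/temperature/water partial rates and integral Gr."""
    ax = _get_ax(ax)
    yr = growth.year(year)
    ax.plot(yr["doy"], yr["g_e"], color="goldenrod", label="photoperiod $g_E$")
    ax.plot(yr["doy"], yr["g_t"], color="firebrick", label="temperature $g_T$")
    ax.plot(yr["doy"], yr["g_w"], color="steelblue", label="soil water $g_W$")
    ax.plot(yr["doy"], yr["gr"], color="black", lw=2, label="integral $Gr$")
    ax.set_xlabel("day of year")
    ax.set_ylabel("growth rate (0-1)")
    ax.set_ylim(0, 1.05)
    ax.set_title(f"partial growth rates, {year}")
    ax.legend(frameon=False)
    return ax


def plot_indices(predicted, observed=None, ax=None):
    """Simulated vs observed standardized ring-width indices by year."""
    ax = _get_ax(ax)
    ax.plot(predicted.index, predicted.values, "o-", label="predicted")
    if observed is not None:
        ax.plot(observed.index, observed.values, "s--", label="observed")
    ax.axhline(1.0, color="grey", lw=0.5)
    ax.set_xlabel("year")
    ax.set_ylabel("ring-width index")
    ax.legend(frameon=False)
    return ax


def plot_pred_obs(table, summary=None, ax=None):
    """Predicted-vs-observed scatter with a dashed 1:1 line."""
    ax = _get_ax(ax)
    ax.scatter(table["predicted"], table["observed"], s=12, alpha=0.6)
    lo = min(table["predicted"].min(), table["observed"].min())
    hi = max(table["predicted"].max(), table["observed"].max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=1, label="1:1")
    if summary is not None and not summary.degenerate:
        xs = np.linspace(lo, hi, 50)
        ax.plot(xs, summary.intercept + summary.slope * xs, "r-", lw=1,
                label=f"OLS ($R^2$={summary.r_squared:.2f})")
    var = table["variable"].iloc[0]
    ax.set_xlabel(f"predicted {var}")
    ax.set_ylabel(f"observed {var}")
    ax.legend(frameon=False)
    return ax


def plot_timing_patterns(pred, obs, span: float = 0.7, ax=None):
    """Per-cell-position timing curves (LOESS) for prediction and
    observation, mirroring the usual cell-position panels."""
    ax = _get_ax(ax)
    for values, color, label in ((pred, "firebrick", "predicted"),
                                 (obs, "steelblue", "observed")):
        x = np.asarray(values["cell_position"], dtype=float)
        y = np.asarray(values.iloc[:, -1], dtype=float)
        ok = np.isfinite(y)
        ax.scatter(x[ok], y[ok], s=8, alpha=0.3, color=color)
        if ok.sum() >= 10:
            gx, gy = loess_pattern(x[ok], y[ok], span=span)
            ax.plot(gx, gy, color=color, lw=2, label=label)
    ax.set_xlabel("cell position")
    ax.set_ylabel("day of year")
    ax.legend(frameon=False)
    return ax
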