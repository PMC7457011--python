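"""Model/Results interface over the VS growth pipeline.

``VSGrowthModel`` is built from daily climate, a site, and (for fitting)
an observed standardized ring-width chronology; ``fit()`` searches the
parameter space and returns ``VSGrowthResults`` holding the selected
parameters, their agreement statistics, the full candidate table, and
convenience methods for simulation, per-cell timing prediction and
plotting — in the spirit of a statsmodels model/results pair.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from . import calibration as _cal
from .cell_timing import extract_cell_timings
from .core import DataError, GrowthSeries, annual_index, simulate_growth
from .params import SiteConfig, VSParameters

__all__ = ["VSGrowthModel", "VSGrowthResults", "DEFAULT_SEARCH_SPACE"]

# default free parameters and bounds; temperature nodes stay inside the
# 4-29 degC plausibility envelope for cold-adapted conifers
DEFAULT_SEARCH_SPACE: dict[str, tuple[float, float]] = {
    "t_opt1": (5.0, 17.0),
    "t_beg": (40.0, 160.0),
}


class VSGrowthModel:
    """Vaganov-Shashkin growth model bound to one site's data.

    Parameters
    ----------
    climate : DataFrame
        Tidy daily weather (``year, doy, temp, precip``).
    site : SiteConfig
        Site location (latitude drives the photoperiod rate).
    chronology : Series, optional
        Observed standardized ring-width indices by year; required for
        :meth:`fit`.
    params : VSParameters, optional
        Baseline parameters; searched parameters override these.
    """

    def __init__(
        self,
        climate: pd.DataFrame,
        site: SiteConfig,
        chronology: pd.Series | None = None,
        params: VSParameters | None = None,
    ) -> None:
        self.climate = climate
        self.site = site
        self.chronology = chronology
        self.params = params or VSParameters()

    @classmethod
    def from_files(
        cls, climate_csv, site_yaml, chronology_csv=None, params_yaml=None
    ) -> "VSGrowthModel":
        from . import io as _io
        from .params import load_params, load_site

        chron = _io.read_chronology(chronology_csv) if chronology_csv else None
        params = load_params(params_yaml) if params_yaml else None
        return cls(_io.read_climate(climate_csv), load_site(site_yaml), chron, params)

    def simulate(self, params: VSParameters | None = None) -> GrowthSeries:
        """Run the daily simulation with the given (or baseline) parameters."""
        return simulate_growth(self.climate, self.site, params or self.params)

    def fit(
        self,
        search_space: Mapping[str, tuple[float, float] | float] | None = None,
        seed: int = 0,
        budget: int = 500,
        refine: bool = True,
    ) -> "VSGrowthResults":
        """Calibrate free parameters against the observed chronology."""
        if self.chronology is None:
            raise DataError("fitting requires an observed chronology")
        space = dict(search_space or DEFAULT_SEARCH_SPACE)
        candidates = _cal.calibrate(
            self.climate,
            self.site,
            self.chronology,
            space,
            base_params=self.params,
            seed=seed,
            budget=budget,
            refine=refine,
        )
        names = sorted(k for k, v in space.items() if not np.isscalar(v))
        fixed = {k: v for k, v in space.items() if np.isscalar(v)}
        base = self.params.replace(**fixed) if fixed else self.params
        best = candidates.iloc[0]
        result = _cal.result_from_row(best, base, names)
        return VSGrowthResults(self, result, candidates, names, seed, budget)


class VSGrowthResults:
    """Fitted-model results: selected parameters, fit statistics,
    candidate ranking, and derived predictions."""

    def __init__(
        self,
        model: VSGrowthModel,
        result: _cal.CalibrationResult,
        candidates: pd.DataFrame,
        searched: list[str],
        seed: int,
        budget: int,
    ) -> None:
        self.model = model
        self.params = result.params
        self.pearson_r = result.pearson_r
        self.p_value = result.p_value
        self.rmse = result.rmse
        self.retained = result.retained
        self.n_years = result.n_years
        self.candidates = candidates
        self.searched = searched
        self.seed = seed
        self.budget = budget
        self._growth: GrowthSeries | None = None

    # -- derived quantities -------------------------------------------------

    def simulate(self) -> GrowthSeries:
        """Daily growth series under the fitted parameters (cached)."""
        if self._growth is None:
            self._growth = self.model.simulate(self.params)
        return self._growth

    def predicted_indices(self) -> pd.Series:
        return annual_index(self.simulate())

    def seasons(self) -> pd.DataFrame:
        """Predicted wood-formation window per year."""
        return self.simulate().seasons

    def cell_timings(self, n_cells: Mapping[int, int]) -> pd.DataFrame:
        """Per-cell division/enlargement timings for each year.

        ``n_cells`` maps year to the observed annual cell production.
        Degenerate (no-growth) years are skipped.
        """
        growth = self.simulate()
        frames = []
        for year, n in n_cells.items():
            start, _ = growth.season(int(year))
            if np.isnan(start):
                continue
            t = extract_cell_timings(growth, int(year), int(n))
            t.insert(0, "year", int(year))
            frames.append(t)
        if not frames:
            raise DataError("no year with a growing season")
        return pd.concat(frames, ignore_index=True)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "VS growth model fit",
            "=" * 46,
            f"site                 {self.model.site.site_id}",
            f"years                {self.n_years}",
            f"candidates scored    {len(self.candidates)} (budget {self.budget}, seed {self.seed})",
            f"searched parameters  {', '.join(self.searched) or '(none)'}",
            "-" * 46,
            f"Pearson r            {self.pearson_r: .4f}",
            f"p-value              {self.p_value: .4g}",
            f"RMSE                 {self.rmse: .4f}",
            f"RMSE < 0.3           {self.rmse < _cal.RMSE_QUALITY_THRESHOLD}",
            f"retained             {self.retained}",
            "-" * 46,
            "parameters:",
        ]
        for field in dataclasses.fields(self.params):
            mark = " *" if field.name in self.searched else ""
            lines.append(f"  {field.name:<18} {getattr(self.params, field.name)}{mark}")
        lines.append("(* searched; others fixed)")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<VSGrowthResults site={self.model.site.site_id!r} "
            f"r={self.pearson_r:.3f} rmse={self.rmse:.3f} retained={self.retained}>"
        )

    # -- plotting -----------------------------------------------------------

    def plot_partial_rates(self, year: int, ax=None):
        from .plotting import plot_partial_rates

        return plot_partial_rates(self.simulate(), year, ax=ax)

    def plot_indices(self, ax=None):
        from .plotting import plot_indices

        return plot_indices(
            self.predicted_indices(), self.model.chronology, ax=ax
        )
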