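"""Synthetic boreal site data with the statistical structure the
pipeline assumes.

Emulates a latitudinal gradient of cold-temperate/boreal conifer sites
(48-54 degrees N, mean annual temperature -3.4 to +1.9 degC, annual
precipitation 626-906 mm): daily weather as an annual temperature
sinusoid with AR(1) noise plus Bernoulli-gamma precipitation; rings of
15-80 tracheids; weekly April-October phase counts forward-simulated
from known per-cell timings; and ring-width series sharing a common
index signal under a negative-exponential age trend.  Everything is
reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cell_timing import extract_cell_timings
from .core import DataError, GrowthSeries, annual_index, simulate_growth
from .params import SiteConfig, VSParameters

__all__ = [
    "SyntheticSiteSpec",
    "DEFAULT_SITES",
    "gen_weather",
    "attach_differentiation",
    "gen_observations",
    "gen_ring_widths",
    "make_site_dataset",
]


@dataclass(frozen=True)
class SyntheticSiteSpec:
    """Generating conditions for one synthetic site."""

    site_id: str
    latitude: float
    longitude: float
    elevation: float
    mean_temp: float            # mean annual temperature, degC
    temp_amplitude: float       # annual sinusoid amplitude, degC
    annual_precip: float        # mean annual precipitation, mm
    wet_day_p: float = 0.45     # probability a day is wet
    gamma_shape: float = 0.7    # shape of wet-day precipitation amounts
    ar1_sigma: float = 3.5      # AR(1) temperature noise SD, degC
    ar1_rho: float = 0.75       # AR(1) lag-1 autocorrelation
    n_years: int = 15
    start_year: int = 2002
    mean_cells: float = 35.0    # mean annual tracheid production
    cell_cv: float = 0.2        # lognormal CV of annual cell counts
    count_noise_sd: float = 0.5  # cell-count observation noise, cells
    diameter_noise_cv: float = 0.08
    n_trees: int = 10

    def __post_init__(self) -> None:
        if self.n_years < 1:
            raise DataError("n_years must be >= 1")
        if not 0.0 <= self.wet_day_p <= 1.0:
            raise DataError("wet_day_p must be in [0, 1]")

    @property
    def site(self) -> SiteConfig:
        return SiteConfig(
            site_id=self.site_id,
            latitude=self.latitude,
            longitude=self.longitude,
            elevation=self.elevation,
        )


# five sites spanning the boreal latitudinal gradient the generator emulates
DEFAULT_SITES: tuple[SyntheticSiteSpec, ...] = (
    SyntheticSiteSpec("SIM", 48.22, 71.25, 338, 1.9, 17.0, 906, mean_cells=45),
    SyntheticSiteSpec("BER", 48.85, 70.33, 611, 0.1, 17.5, 886, mean_cells=40),
    SyntheticSiteSpec("MIS", 49.72, 71.93, 342, 0.3, 18.0, 755, mean_cells=35),
    SyntheticSiteSpec("DAN", 50.68, 72.18, 487, -1.3, 18.5, 735, mean_cells=28),
    SyntheticSiteSpec("MIR", 53.78, 72.87, 384, -3.4, 19.0, 626, mean_cells=20),
)


def _days_in_year(year: int) -> int:
    leap = year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
    return 366 if leap else 365


def gen_weather(spec: SyntheticSiteSpec, seed: int = 0) -> pd.DataFrame:
    """Daily temperature and precipitation for ``spec.n_years`` years.

    Temperature is a sinusoid (minimum in late January, DOY 27) plus
    stationary AR(1) noise; precipitation is Bernoulli wet-day occurrence
    times gamma-distributed amounts whose scale is set so the expected
    annual total matches the spec.
    """
    rng = np.random.default_rng(seed)
    frames = []
    e_prev = rng.normal(0.0, spec.ar1_sigma) if spec.ar1_sigma > 0 else 0.0
    innov_sd = spec.ar1_sigma * np.sqrt(max(1.0 - spec.ar1_rho**2, 0.0))
    if spec.wet_day_p > 0:
        scale = spec.annual_precip / (365.25 * spec.wet_day_p * spec.gamma_shape)
    else:
        scale = 0.0
    for year in range(spec.start_year, spec.start_year + spec.n_years):
        n = _days_in_year(year)
        doy = np.arange(1, n + 1)
        seasonal = spec.mean_temp - spec.temp_amplitude * np.cos(
            2 * np.pi * (doy - 27) / 365.25
        )
        if spec.ar1_sigma > 0:
            noise = np.empty(n)
            for i in range(n):
                e_prev = spec.ar1_rho * e_prev + rng.normal(0.0, innov_sd)
                noise[i] = e_prev
        else:
            noise = np.zeros(n)
        wet = rng.random(n) < spec.wet_day_p
        precip = np.where(
            wet, rng.gamma(spec.gamma_shape, scale, size=n), 0.0
        )
        frames.append(
            pd.DataFrame(
                {"year": year, "doy": doy, "temp": seasonal + noise, "precip": precip}
            )
        )
    return pd.concat(frames, ignore_index=True)


# -- differentiation schedule ------------------------------------------------
# Enlargement lasts ~8 days for the first-formed cells and lengthens toward
# the ring boundary; wall thickening lasts ~15 days in earlywood and up to
# ~40 days for the last latewood cells.  Cell diameter is the product of an
# enlargement-rate profile that declines across the ring (3.5 -> 0.8 um/day)
# and the enlargement duration, giving ~30 um earlywood and ~11 um latewood
# tracheids.

def attach_differentiation(
    timings: pd.DataFrame,
    enl_base: float = 8.0,
    enl_slope: float = 6.0,
    wall_base: float = 15.0,
    wall_slope: float = 25.0,
    rate_max: float = 3.5,
    rate_min: float = 0.8,
) -> pd.DataFrame:
    """Extend division/enlargement timings with wall-deposition and
    maturation days plus noise-free cell diameters.

    Adds ``t_enlarge`` (alias of ``enlargement_doy``), ``dur_enlarge``,
    ``t_wall``, ``t_mature``, and ``diameter_um``.
    """
    out = timings.copy()
    n = len(out)
    frac = (out["cell_position"].to_numpy(dtype=float) - 1) / max(n - 1, 1)
    dur_enl = np.round(enl_base + enl_slope * frac).astype(int)
    dur_wall = np.round(wall_base + wall_slope * frac).astype(int)
    out["t_enlarge"] = out["enlargement_doy"]
    out["dur_enlarge"] = dur_enl
    out["t_wall"] = out["t_enlarge"] + dur_enl
    out["t_mature"] = out["t_wall"] + dur_wall
    rate = rate_max - (rate_max - rate_min) * frac
    out["diameter_um"] = rate * dur_enl
    return out


def _sampling_doys(interval: int, first: int = 91, last: int = 304) -> np.ndarray:
    if not 5 <= interval <= 15:
        raise DataError(f"sampling interval {interval} outside [5, 15] days")
    return np.arange(first, last + 1, interval)


def gen_observations(
    growth: GrowthSeries,
    year: int,
    true_timings: pd.DataFrame,
    sampling_interval: int = 7,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_trees: int = 10,
    cambial_baseline: float = 4.0,
    cambial_amplitude: float = 5.0,
    diameter_noise_cv: float = 0.08,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward-simulate microcore sampling from known per-cell timings.

    On each sampling day the phase counts follow from interval
    membership: a cell is enlarging on ``[t_enlarge, t_wall)``, wall
    thickening on ``[t_wall, t_mature)`` and mature from ``t_mature``
    onward.  The cambial count is a dormant baseline plus a swelling
    proportional to the normalized daily growth rate.  Per-tree counts
    get integer-rounded Gaussian noise truncated at zero; tracheidogram
    diameters get lognormal noise.

    Returns ``(counts, anatomy)`` tidy frames.
    """
    if true_timings.empty:
        raise DataError("empty timing set")
    rng = np.random.default_rng(seed)
    doys = _sampling_doys(sampling_interval)
    yr = growth.year(year)
    gr = yr.set_index("doy")["gr"]
    gr_max = gr.max()
    t_enl = true_timings["t_enlarge"].to_numpy(dtype=float)
    t_wall = true_timings["t_wall"].to_numpy(dtype=float)
    t_mat = true_timings["t_mature"].to_numpy(dtype=float)
    site_id = getattr(growth, "site_id", "SYN")
    rows = []
    for d in doys:
        activity = float(gr.get(d, 0.0)) / gr_max if gr_max > 0 else 0.0
        cambial = cambial_baseline + cambial_amplitude * activity
        n_enl = int(np.sum((t_enl <= d) & (d < t_wall)))
        n_wall = int(np.sum((t_wall <= d) & (d < t_mat)))
        n_mat = int(np.sum(t_mat <= d))
        for tree in range(1, n_trees + 1):
            # counting error applies to cells that exist; an empty phase is
            # unambiguous under the microscope and stays 0
            noisy = [
                max(v + round(rng.normal(0.0, noise_sd)), 0)
                if noise_sd > 0 and v > 0
                else v
                for v in (cambial, n_enl, n_wall, n_mat)
            ]
            rows.append(
                {
                    "site_id": site_id,
                    "tree_id": f"T{tree:02d}",
                    "year": year,
                    "doy": int(d),
                    "n_cambial": noisy[0],
                    "n_enlarging": noisy[1],
                    "n_wall": noisy[2],
                    "n_mature": noisy[3],
                }
            )
    counts = pd.DataFrame(rows)
    anat_rows = []
    diam = true_timings["diameter_um"].to_numpy(dtype=float)
    for tree in range(1, n_trees + 1):
        noise = (
            rng.lognormal(0.0, diameter_noise_cv, size=diam.size)
            if diameter_noise_cv > 0
            else np.ones(diam.size)
        )
        for pos, d_um in zip(true_timings["cell_position"], diam * noise):
            anat_rows.append(
                {
                    "site_id": site_id,
                    "tree_id": f"T{tree:02d}",
                    "year": year,
                    "file_id": 1,
                    "cell_position": int(pos),
                    "diameter_um": float(d_um),
                    "wall_um": np.nan,
                }
            )
    return counts, pd.DataFrame(anat_rows)


def gen_ring_widths(
    common_index: pd.Series,
    n_trees: int = 10,
    noise_sigma: float = 0.1,
    trend_width: float = 0.8,
    trend_decay: float = 0.03,
    trend_floor: float = 0.4,
    seed: int = 0,
) -> dict[str, pd.Series]:
    """Per-tree ring widths: negative-exponential trend x common signal x
    lognormal noise, seeded."""
    if n_trees < 1:
        raise DataError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    years = common_index.index.to_numpy()
    t = years - years[0]
    # missing-ring convention: a no-growth year is measured as a locally
    # absent ring of nominal 0.01 width, never zero
    common_index = common_index.clip(lower=0.01)
    out = {}
    for tree in range(1, n_trees + 1):
        a = trend_width * rng.uniform(0.7, 1.3)
        b = trend_decay * rng.uniform(0.5, 1.5)
        c = trend_floor * rng.uniform(0.8, 1.2)
        trend = a * np.exp(-b * t) + c
        noise = (
            rng.lognormal(0.0, noise_sigma, size=t.size)
            if noise_sigma > 0
            else np.ones(t.size)
        )
        widths = trend * common_index.to_numpy() * noise
        out[f"T{tree:02d}"] = pd.Series(widths, index=years, name="width_mm")
    return out


def annual_cell_counts(spec: SyntheticSiteSpec, seed: int = 0) -> pd.Series:
    """Annual tracheid production: lognormal around the site mean,
    clipped to the realistic 15-80 cell range."""
    rng = np.random.default_rng(seed)
    years = np.arange(spec.start_year, spec.start_year + spec.n_years)
    sigma = np.sqrt(np.log(1 + spec.cell_cv**2))
    raw = rng.lognormal(np.log(spec.mean_cells) - sigma**2 / 2, sigma, len(years))
    return pd.Series(np.clip(np.round(raw), 15, 80).astype(int), index=years)


def make_site_dataset(
    spec: SyntheticSiteSpec,
    params: VSParameters | None = None,
    seed: int = 0,
    sampling_interval: int = 7,
    index_noise_sigma: float = 0.1,
) -> dict:
    """Full forward chain for one site: weather -> growth -> timings ->
    observations -> ring widths.

    Sub-seeds are derived deterministically from ``seed``.  Returns a
    dict with keys ``spec, params, climate, growth, n_cells, timings
    (per-year true timing frames), counts, anatomy, ring_widths,
    true_index``.
    """
    params = params or VSParameters()
    ss = np.random.SeedSequence(seed)
    s_weather, s_cells, s_obs, s_rw = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    )
    climate = gen_weather(spec, seed=s_weather)
    growth = simulate_growth(climate, spec.site, params)
    growth.site_id = spec.site_id
    n_cells = annual_cell_counts(spec, seed=s_cells)
    timings = {}
    counts_frames = []
    anat_frames = []
    for i, year in enumerate(growth.years):
        start, _ = growth.season(year)
        if np.isnan(start):
            continue
        t = extract_cell_timings(growth, int(year), int(n_cells.loc[year]))
        t = attach_differentiation(t)
        timings[int(year)] = t
        counts, anat = gen_observations(
            growth,
            int(year),
            t,
            sampling_interval=sampling_interval,
            noise_sd=spec.count_noise_sd,
            seed=s_obs + i,
            n_trees=spec.n_trees,
            diameter_noise_cv=spec.diameter_noise_cv,
        )
        counts_frames.append(counts)
        anat_frames.append(anat)
    true_index = annual_index(growth)
    rng = np.random.default_rng(s_rw)
    noisy_index = true_index + (
        rng.normal(0.0, index_noise_sigma, len(true_index))
        if index_noise_sigma > 0
        else 0.0
    )
    ring_widths = gen_ring_widths(
        true_index, n_trees=spec.n_trees, noise_sigma=0.1, seed=s_rw
    )
    return {
        "spec": spec,
        "params": params,
        "climate": climate,
        "growth": growth,
        "n_cells": n_cells,
        "timings": timings,
        "counts": pd.concat(counts_frames, ignore_index=True)
        if counts_frames
        else pd.DataFrame(),
        "anatomy": pd.concat(anat_frames, ignore_index=True)
        if anat_frames
        else pd.DataFrame(),
        "ring_widths": ring_widths,
        "true_index": true_index,
        "observed_index": noisy_index,
    }
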