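"""Daily Vaganov-Shashkin growth simulation.

The integral tree-ring growth rate is ``Gr = g_E * min(g_T, g_W)``: the
photoperiod rate scales whichever of the temperature and soil-water
partial rates is currently limiting.  Growth starts once the degree-day
sum above ``t_min`` reaches ``t_beg`` with all three partial rates
positive, and ends at the first post-peak day on which Gr falls below
the critical rate ``v_cr``.  Outside the growing season soil water
content is held constant (the model does not track dormancy soil
moisture) while snowfall keeps accumulating in the snowpack.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .params import ConfigError, SiteConfig, VSParameters

__all__ = [
    "day_length",
    "photoperiod_rate",
    "trapezoid_rate",
    "soil_water_step",
    "growth_onset",
    "growth_cessation",
    "simulate_growth",
    "annual_index",
    "GrowthSeries",
]


class DataError(ValueError):
    """Raised for malformed or incomplete input data."""


# ---------------------------------------------------------------------------
# solar geometry

_ZENITH_RISE = np.cos(np.radians(90.833))  # refraction + solar disc


def _declination(doy):
    """Solar declination (radians) from the Spencer Fourier series."""
    g = 2.0 * np.pi * (np.asarray(doy, dtype=float) - 1.0) / 365.0
    return (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.001480 * np.sin(3 * g)
    )


def day_length(latitude: float, doy) -> np.ndarray | float:
    """Hours of daylight (sunrise to sunset, incl. refraction).

    Polar day and night clamp to 24 and 0 hours respectively.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ConfigError(f"latitude {latitude} outside [-90, 90]")
    decl = _declination(doy)
    lat = np.radians(latitude)
    cos_ha = (_ZENITH_RISE - np.sin(lat) * np.sin(decl)) / (
        np.cos(lat) * np.cos(decl)
    )
    cos_ha = np.clip(cos_ha, -1.0, 1.0)
    out = 24.0 / np.pi * np.arccos(cos_ha)
    if np.isscalar(doy):
        return float(out)
    return out


def photoperiod_rate(latitude: float, doy) -> np.ndarray | float:
    """Photoperiod partial growth rate: day length over its annual maximum.

    Equals 1 at the summer solstice (and all year at the equator, where
    day length is constant).
    """
    annual_max = float(np.max(day_length(latitude, np.arange(1, 366))))
    return day_length(latitude, doy) / annual_max


# ---------------------------------------------------------------------------
# environmental responses

def trapezoid_rate(x, x1: float, x2: float, x3: float, x4: float):
    """Piecewise-linear trapezoidal response on nodes ``x1 < x2 <= x3 < x4``.

    0 outside ``(x1, x4)``, 1 on the plateau ``[x2, x3]``, linear on the
    rising and falling limbs.
    """
    if not (x1 < x2 <= x3 < x4):
        raise ConfigError(f"trapezoid nodes must be ordered, got {(x1, x2, x3, x4)}")
    out = np.interp(np.asarray(x, dtype=float), [x1, x2, x3, x4], [0.0, 1.0, 1.0, 0.0])
    if np.isscalar(x):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# soil water bucket (reference step; the simulation uses the numba kernel
# below, which is asserted against this function in the test suite)

def soil_water_step(
    state: dict,
    temp: float,
    precip: float,
    params: VSParameters,
    daylen: float,
) -> dict:
    """Advance the soil bucket by one day.

    ``state`` holds ``swc_sim`` (V/Vs) and ``snowpack`` (mm SWE).  Returns a
    new state dict that additionally reports each flux in mm (``snowfall``,
    ``throughfall``, ``melt``, ``pet``, ``drainage``) and the clamping
    ``residue`` so a mass-balance ledger can be closed exactly:

    ``delta(swc*root_depth) + delta(snowpack)
      = throughfall - pet - drainage - residue``.
    """
    if not (np.isfinite(temp) and np.isfinite(precip)):
        raise DataError(f"non-finite climate values: temp={temp}, precip={precip}")
    swc = float(state["swc_sim"])
    snow = float(state["snowpack"])
    p = params

    if p.soil_melting_block and temp <= p.t_snow:
        snowfall, throughfall = precip, 0.0
    else:
        snowfall, throughfall = 0.0, (1.0 - p.k_intercept) * precip
    snow += snowfall
    if p.soil_melting_block:
        melt = min(snow, p.k_melt * max(temp - p.t_snow, 0.0))
    else:
        melt = 0.0
    snow -= melt
    pet = p.k_pet * max(temp, 0.0) * daylen / 12.0
    drainage = p.k_drain * max(swc - p.w_max, 0.0) * p.root_depth
    raw = swc + (throughfall + melt - pet - drainage) / p.root_depth
    new_swc = min(max(raw, 0.0), 1.0)
    residue = (raw - new_swc) * p.root_depth
    return {
        "swc_sim": new_swc,
        "snowpack": snow,
        "snowfall": snowfall,
        "throughfall": throughfall,
        "melt": melt,
        "pet": pet,
        "drainage": drainage,
        "residue": residue,
    }


# ---------------------------------------------------------------------------
# numba kernel: one calendar year from growth onset to 31 December

@njit(cache=True)
def _season_kernel(
    temp,
    precip,
    daylen,
    gt,
    ge,
    i0,
    swc0,
    snow0,
    t_snow,
    k_intercept,
    k_melt,
    k_pet,
    k_drain,
    w_max,
    root_depth,
    melting_block,
    w1,
    w2,
    w3,
    w4,
):  # pragma: no cover - exercised via simulate_growth
    n = temp.shape[0]
    swc = np.empty(n)
    snow = np.empty(n)
    gw = np.empty(n)
    gr = np.empty(n)
    gw_frozen = _trapezoid_scalar(swc0, w1, w2, w3, w4)
    s = swc0
    sp = snow0
    for i in range(n):
        if i < i0:
            # dormancy: snow accumulates and melts by degree-days, but the
            # soil is frozen, so meltwater runs off and swc stays constant
            if melting_block:
                if temp[i] <= t_snow:
                    sp += precip[i]
                else:
                    m = k_melt * (temp[i] - t_snow)
                    sp -= m if m < sp else sp
            swc[i] = s
            snow[i] = sp
            gw[i] = gw_frozen
            gr[i] = 0.0
        else:
            if melting_block and temp[i] <= t_snow:
                snowfall = precip[i]
                through = 0.0
            else:
                snowfall = 0.0
                through = (1.0 - k_intercept) * precip[i]
            sp += snowfall
            melt = 0.0
            if melting_block:
                m = k_melt * (temp[i] - t_snow)
                if m > 0.0:
                    melt = m if m < sp else sp
            sp -= melt
            pet = k_pet * (temp[i] if temp[i] > 0.0 else 0.0) * daylen[i] / 12.0
            drain = k_drain * (s - w_max if s > w_max else 0.0) * root_depth
            s = s + (through + melt - pet - drain) / root_depth
            if s < 0.0:
                s = 0.0
            elif s > 1.0:
                s = 1.0
            swc[i] = s
            snow[i] = sp
            gw[i] = _trapezoid_scalar(s, w1, w2, w3, w4)
            lim = gt[i] if gt[i] < gw[i] else gw[i]
            gr[i] = ge[i] * lim
    return swc, snow, gw, gr


@njit(cache=True)
def _dormant_snow(temp, precip, snow0, t_snow, k_melt, melting_block):  # pragma: no cover
    """Snowpack trajectory over a dormant stretch: accumulation plus
    degree-day melt whose water runs off over the frozen soil."""
    n = temp.shape[0]
    snow = np.empty(n)
    sp = snow0
    for i in range(n):
        if melting_block:
            if temp[i] <= t_snow:
                sp += precip[i]
            else:
                m = k_melt * (temp[i] - t_snow)
                sp -= m if m < sp else sp
        snow[i] = sp
    return snow


@njit(cache=True)
def _trapezoid_scalar(x, x1, x2, x3, x4):  # pragma: no cover
    if x <= x1 or x >= x4:
        return 0.0
    if x < x2:
        return (x - x1) / (x2 - x1)
    if x <= x3:
        return 1.0
    return (x4 - x) / (x4 - x3)


# ---------------------------------------------------------------------------
# season boundaries

def growth_onset(
    temp: np.ndarray,
    params: VSParameters,
    g_e: np.ndarray,
    g_w: np.ndarray,
) -> int | None:
    """First day index at which growth can start, or ``None``.

    Requires the degree-day sum ``sum(max(temp - t_min, 0))`` accumulated
    from day 1 to reach ``t_beg`` while all three partial rates are
    positive on that day.
    """
    temp = np.asarray(temp, dtype=float)
    if temp.shape[0] < 365:
        raise DataError(f"need a full year of climate, got {temp.shape[0]} days")
    forcing = np.cumsum(np.maximum(temp - params.t_min, 0.0))
    gt = trapezoid_rate(temp, params.t_min, params.t_opt1, params.t_opt2, params.t_max)
    ok = (forcing >= params.t_beg) & (gt > 0) & (np.asarray(g_w) > 0) & (np.asarray(g_e) > 0)
    idx = np.nonzero(ok)[0]
    return int(idx[0]) if idx.size else None


def growth_cessation(gr: np.ndarray, start: int, v_cr: float) -> int | None:
    """Index of the season's end day.

    The season ends on the first day strictly after the within-season
    maximum of Gr on which Gr drops below ``v_cr``; Gr is forced to zero
    on the days after it.  With ``v_cr == 0`` the season runs to the last
    day with positive Gr.  If Gr never exceeds ``v_cr`` the season has
    length 0 and ``None`` is returned (callers flag the year).
    """
    gr = np.asarray(gr, dtype=float)
    season = gr[start:]
    if season.size == 0:
        return None
    if v_cr == 0.0:
        pos = np.nonzero(season > 0)[0]
        return start + int(pos[-1]) if pos.size else None
    if season.max() <= v_cr:
        return None
    peak = int(np.argmax(season))
    below = np.nonzero(season[peak + 1:] < v_cr)[0]
    if below.size == 0:
        return start + season.size - 1
    return start + peak + 1 + int(below[0])


# ---------------------------------------------------------------------------
# result container

@dataclass
class GrowthSeries:
    """Daily VS simulation output plus per-year season boundaries.

    ``data`` is tidy with columns ``year, doy, g_e, g_t, g_w, gr,
    swc_sim, snowpack``; ``seasons`` has ``year, start_doy, end_doy``
    (NaN where no growth occurred — degenerate years are kept, flagged
    by NaN boundaries and an all-zero Gr).
    """

    data: pd.DataFrame
    seasons: pd.DataFrame

    def year(self, year: int) -> pd.DataFrame:
        out = self.data[self.data["year"] == year]
        if out.empty:
            raise KeyError(f"year {year} not simulated")
        return out.reset_index(drop=True)

    def season(self, year: int) -> tuple[float, float]:
        row = self.seasons[self.seasons["year"] == year]
        if row.empty:
            raise KeyError(f"year {year} not simulated")
        return float(row["start_doy"].iloc[0]), float(row["end_doy"].iloc[0])

    @property
    def years(self) -> np.ndarray:
        return self.seasons["year"].to_numpy()

    def to_csv(self, path: str | Path, **kwargs) -> None:
        self.data.to_csv(path, index=False, **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GrowthSeries":
        data = pd.read_csv(path, comment="#")
        seasons = _seasons_from_data(data)
        return cls(data=data, seasons=seasons)


def _seasons_from_data(data: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for year, grp in data.groupby("year"):
        pos = grp[grp["gr"] > 0]
        if pos.empty:
            rows.append({"year": year, "start_doy": np.nan, "end_doy": np.nan})
        else:
            rows.append(
                {
                    "year": year,
                    "start_doy": float(pos["doy"].iloc[0]),
                    "end_doy": float(pos["doy"].iloc[-1]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full simulation

def _days_in_year(year: int) -> int:
    leap = year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)
    return 366 if leap else 365


def _validate_climate(climate: pd.DataFrame) -> None:
    required = {"year", "doy", "temp", "precip"}
    missing = required - set(climate.columns)
    if missing:
        raise DataError(f"climate table missing columns: {sorted(missing)}")
    if not np.isfinite(climate[["temp", "precip"]].to_numpy()).all():
        raise DataError("climate contains non-finite temp/precip values")
    if (climate["precip"] < 0).any():
        raise DataError("negative precipitation")
    gaps = []
    for year, grp in climate.groupby("year"):
        doys = grp["doy"].to_numpy()
        expected = np.arange(1, _days_in_year(int(year)) + 1)
        if doys.shape[0] != expected.shape[0] or not np.array_equal(doys, expected):
            missing_doys = sorted(set(expected) - set(doys))
            gaps.append((int(year), missing_doys[:5]))
    if gaps:
        raise DataError(f"climate has missing days (year, first gaps): {gaps}")


def prepare_climate(climate: pd.DataFrame, site: SiteConfig) -> list[dict]:
    """Validate climate and precompute per-year arrays for fast repeated
    simulation (used by calibration, which re-simulates thousands of
    parameter candidates against the same weather)."""
    _validate_climate(climate)
    climate = climate.sort_values(["year", "doy"])
    prepared = []
    for year, grp in climate.groupby("year", sort=True):
        doys = grp["doy"].to_numpy(dtype=int)
        daylen = day_length(site.latitude, doys)
        prepared.append(
            {
                "year": int(year),
                "doys": doys,
                "temp": grp["temp"].to_numpy(dtype=float),
                "precip": grp["precip"].to_numpy(dtype=float),
                "daylen": daylen,
                "ge": daylen / daylen.max(),
            }
        )
    return prepared


def _simulate_year(
    yr: dict, p: VSParameters, swc_carry: float, snow_carry: float
) -> tuple[dict, float, float]:
    """One calendar year of the VS model given carry-over soil/snow state."""
    temp, precip = yr["temp"], yr["precip"]
    doys, daylen, ge = yr["doys"], yr["daylen"], yr["ge"]
    n = temp.shape[0]
    gt = trapezoid_rate(temp, p.t_min, p.t_opt1, p.t_opt2, p.t_max)
    gw_frozen = trapezoid_rate(swc_carry, p.w_min, p.w_opt1, p.w_opt2, p.w_max)
    onset = growth_onset(temp, p, ge, np.full(n, gw_frozen))
    if onset is None:
        # fully dormant year: snow accumulates/melts, soil frozen
        snow = _dormant_snow(
            temp, precip, snow_carry, p.t_snow, p.k_melt, p.soil_melting_block
        )
        swc = np.full(n, swc_carry)
        gw = np.full(n, gw_frozen)
        gr = np.zeros(n)
        start_doy = end_doy = np.nan
    else:
        swc, snow, gw, gr = _season_kernel(
            temp, precip, daylen, gt, ge, onset, swc_carry, snow_carry,
            p.t_snow, p.k_intercept, p.k_melt, p.k_pet, p.k_drain,
            p.w_max, p.root_depth, p.soil_melting_block,
            p.w_min, p.w_opt1, p.w_opt2, p.w_max,
        )
        end = growth_cessation(gr, onset, p.v_cr)
        if end is None:
            # season of length 0: Gr never exceeded v_cr
            gr[:] = 0.0
            start_doy = end_doy = np.nan
            end = onset
        else:
            gr[end + 1:] = 0.0
            start_doy = float(doys[onset])
            end_doy = float(doys[end])
        # post-season dormancy: freeze soil, snow accumulates/melts
        if end + 1 < n:
            swc[end + 1:] = swc[end]
            gw[end + 1:] = trapezoid_rate(
                swc[end], p.w_min, p.w_opt1, p.w_opt2, p.w_max
            )
            snow[end + 1:] = _dormant_snow(
                temp[end + 1:], precip[end + 1:], snow[end],
                p.t_snow, p.k_melt, p.soil_melting_block,
            )
    out = {
        "gt": gt,
        "gw": gw,
        "gr": gr,
        "swc": swc,
        "snow": snow,
        "start_doy": start_doy,
        "end_doy": end_doy,
    }
    return out, float(swc[-1]), float(snow[-1])


def annual_growth_sums(prepared: list[dict], params: VSParameters) -> pd.Series:
    """Annual Gr sums for precomputed climate (fast calibration path)."""
    snow_carry = 0.0
    sums = {}
    for yr in prepared:
        res, _, snow_carry = _simulate_year(yr, params, params.w_init, snow_carry)
        sums[yr["year"]] = res["gr"].sum()
    return pd.Series(sums)


def simulate_growth(
    climate: pd.DataFrame,
    site: SiteConfig,
    params: VSParameters,
) -> GrowthSeries:
    """Run the VS model over every complete year in ``climate``.

    ``climate`` is tidy daily data with columns ``year, doy, temp, precip``
    sorted by date.  Soil water content carries over between years and is
    frozen during dormancy; snowpack accumulates year-round.
    """
    prepared = prepare_climate(climate, site)
    p = params
    frames = []
    season_rows = []
    snow_carry = 0.0
    for yr in prepared:
        # dormancy soil water is the per-site winter constant w_init every
        # year; only the snowpack carries over between years
        res, _, snow_carry = _simulate_year(yr, p, p.w_init, snow_carry)
        frames.append(
            pd.DataFrame(
                {
                    "year": yr["year"],
                    "doy": yr["doys"],
                    "g_e": yr["ge"],
                    "g_t": res["gt"],
                    "g_w": res["gw"],
                    "gr": res["gr"],
                    "swc_sim": res["swc"],
                    "snowpack": res["snow"],
                }
            )
        )
        season_rows.append(
            {"year": yr["year"], "start_doy": res["start_doy"], "end_doy": res["end_doy"]}
        )
    return GrowthSeries(
        data=pd.concat(frames, ignore_index=True),
        seasons=pd.DataFrame(season_rows),
    )


def annual_index(growth: GrowthSeries) -> pd.Series:
    """Simulated ring-width index: annual Gr sums normalized to mean 1.

    Degenerate (no-growth) years contribute an index of 0.
    """
    sums = growth.data.groupby("year")["gr"].sum()
    if len(sums) < 2:
        raise DataError("annual_index needs at least 2 simulated years")
    mean = sums.mean()
    if mean == 0:
        raise DataError("all simulated years have zero growth")
    out = sums / mean
    out.name = "index"
    return out
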