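"""Independent reference implementations used as test oracles.

These deliberately re-derive quantities by a different route than the
package (different formulas, naive loops, explicit ledgers) so agreement
is informative.
"""

from __future__ import annotations

import numpy as np


def noaa_day_length(latitude: float, doy: int, year: int = 2015) -> float:
    """Daylight hours from the NOAA solar calculator algorithm
    (Julian-century ephemeris: mean longitude/anomaly, equation of
    center, apparent longitude, corrected obliquity)."""
    # Julian day for 00:00 UT; 2451544.5 = 2000-01-01T00:00
    days_per_year = 366 if year % 4 == 0 and (year % 100 != 0 or year % 400 == 0) else 365
    assert 1 <= doy <= days_per_year
    y = year - 2000
    leap_days = (y + 3) // 4  # leap days between 2000 and `year` (2000 incl.)
    jd = 2451544.5 + 365.0 * y + leap_days + (doy - 1) + 0.5
    jc = (jd - 2451545.0) / 36525.0
    l0 = np.mod(280.46646 + jc * (36000.76983 + 0.0003032 * jc), 360.0)
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    mrad = np.radians(m)
    eq_center = (
        np.sin(mrad) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(2 * mrad) * (0.019993 - 0.000101 * jc)
        + np.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + eq_center
    app_long = true_long - 0.00569 - 0.00478 * np.sin(np.radians(125.04 - 1934.136 * jc))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos(np.radians(125.04 - 1934.136 * jc))
    decl = np.degrees(
        np.arcsin(np.sin(np.radians(obliq)) * np.sin(np.radians(app_long)))
    )
    lat_r, decl_r = np.radians(latitude), np.radians(decl)
    cos_ha = (
        np.cos(np.radians(90.833)) / (np.cos(lat_r) * np.cos(decl_r))
        - np.tan(lat_r) * np.tan(decl_r)
    )
    cos_ha = np.clip(cos_ha, -1.0, 1.0)
    ha = np.degrees(np.arccos(cos_ha))
    return float(8.0 * ha / 60.0)  # 2*HA deg -> minutes (4 min/deg) -> hours


def water_balance_ledger(
    swc0: float, snow0: float, steps: list[dict], root_depth: float
) -> float:
    """Largest daily mass-balance violation (mm) over a step trajectory.

    Each step dict holds the fluxes reported by ``soil_water_step`` plus
    the resulting state; checks
    delta(swc*depth) + delta(snow) == snowfall + throughfall - pet
    - drainage - residue (melt is an internal transfer).
    """
    worst = 0.0
    prev_swc, prev_snow = swc0, snow0
    for s in steps:
        lhs = (s["swc_sim"] - prev_swc) * root_depth + (s["snowpack"] - prev_snow)
        rhs = (
            s["snowfall"] + s["throughfall"] - s["pet"] - s["drainage"] - s["residue"]
        )
        worst = max(worst, abs(lhs - rhs))
        prev_swc, prev_snow = s["swc_sim"], s["snowpack"]
    return worst


def scan_onset(temp, t_min, t_beg, gt, gw, ge):
    """Naive day-by-day scan for the growth-initiation day index."""
    total = 0.0
    for i in range(len(temp)):
        total += max(temp[i] - t_min, 0.0)
        if total >= t_beg and gt[i] > 0 and gw[i] > 0 and ge[i] > 0:
            return i
    return None


def scan_cessation(gr, start, v_cr):
    """Naive scan: first index after the season argmax with gr < v_cr."""
    season = list(gr[start:])
    if not season:
        return None
    if v_cr == 0.0:
        pos = [i for i, g in enumerate(season) if g > 0]
        return start + pos[-1] if pos else None
    if max(season) <= v_cr:
        return None
    peak = season.index(max(season))
    for i in range(peak + 1, len(season)):
        if season[i] < v_cr:
            return start + i
    return start + len(season) - 1


def scan_cell_timings(doys, gr, n_cells):
    """Naive per-cell cumulative-threshold scan (division/enlargement)."""
    total = float(np.sum(gr))
    q = total / n_cells
    cum = np.cumsum(gr)
    enlargement = []
    for i in range(1, n_cells + 1):
        thr = i * q
        day = None
        for k in range(len(doys)):
            if cum[k] >= thr:
                day = doys[k]
                break
        if day is None:
            day = doys[-1]
        enlargement.append(day)
    division = [doys[0]] + enlargement[:-1]
    return np.array(division), np.array(enlargement)


def window_means(doys, gr, division, enlargement):
    """Per-cell mean gr over the inclusive cambial residence window."""
    lookup = {int(d): g for d, g in zip(doys, gr)}
    out = []
    for d0, d1 in zip(division, enlargement):
        vals = [lookup[d] for d in range(int(d0), int(d1) + 1)]
        out.append(sum(vals) / len(vals))
    return np.array(out)


def ols_normal_equations(x, y):
    """Slope/intercept/r^2 via explicit normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (intercept + slope * x)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return slope, intercept, 1.0 - ss_res / ss_tot


def pearson_textbook(x, y):
    """Pearson r and two-sided p from the textbook formulas."""
    from scipy.stats import beta

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xm, ym = x - x.mean(), y - y.mean()
    r = float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))
    # p from the exact null distribution of r (Beta on [-1, 1])
    ab = n / 2.0 - 1.0
    p = float(2.0 * beta.cdf(-abs(r), ab, ab, loc=-1.0, scale=2.0))
    return r, p
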