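"""Trapezoidal responses, the soil bucket, season boundaries, and the
daily growth simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vsxylo.core import (
    DataError,
    annual_index,
    day_length,
    growth_cessation,
    growth_onset,
    simulate_growth,
    soil_water_step,
    trapezoid_rate,
)
from vsxylo.params import ConfigError, SiteConfig, VSParameters
from vsxylo.synthetic import DEFAULT_SITES, gen_weather

from oracles import scan_cessation, scan_onset, water_balance_ledger


# ---------------------------------------------------------------------------
# trapezoid

class TestTrapezoid:
    def test_anchor_values(self, default_params):
        p = default_params
        nodes = (p.t_min, p.t_opt1, p.t_opt2, p.t_max)
        assert trapezoid_rate(p.t_min, *nodes) == 0.0
        assert trapezoid_rate(p.t_max, *nodes) == 0.0
        assert trapezoid_rate(p.t_opt1, *nodes) == 1.0
        assert trapezoid_rate(p.t_opt2, *nodes) == 1.0
        assert trapezoid_rate((p.t_min + p.t_opt1) / 2, *nodes) == pytest.approx(0.5)
        assert trapezoid_rate((p.t_opt2 + p.t_max) / 2, *nodes) == pytest.approx(0.5)

    def test_outside_support_is_zero(self):
        assert trapezoid_rate(-40.0, 4, 10, 20, 29) == 0.0
        assert trapezoid_rate(45.0, 4, 10, 20, 29) == 0.0

    def test_degenerate_plateau_allowed(self):
        assert trapezoid_rate(10.0, 4, 10, 10, 29) == 1.0

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ConfigError):
            trapezoid_rate(5.0, 10, 4, 20, 29)

    @given(x=st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_bounded(self, x):
        r = trapezoid_rate(x, 4.0, 10.0, 20.0, 29.0)
        assert 0.0 <= r <= 1.0


# ---------------------------------------------------------------------------
# soil bucket

class TestSoilBucket:
    def test_all_snow_day(self, default_params):
        state = {"swc_sim": 0.3, "snowpack": 0.0}
        out = soil_water_step(state, temp=-10.0, precip=5.0, params=default_params, daylen=8.0)
        assert out["snowpack"] == pytest.approx(5.0)
        assert out["pet"] == 0.0  # PET clamped at T <= 0
        assert out["swc_sim"] == pytest.approx(0.3)

    def test_melt_capped_by_store(self, default_params):
        p = default_params.replace(k_melt=3.0)
        state = {"swc_sim": 0.3, "snowpack": 10.0}
        out = soil_water_step(state, temp=5.0, precip=0.0, params=p, daylen=12.0)
        assert out["melt"] == pytest.approx(10.0)  # 15 mm potential, 10 available
        assert out["snowpack"] == pytest.approx(0.0)

    def test_block_off_disables_snow(self, default_params):
        p = default_params.replace(soil_melting_block=False)
        state = {"swc_sim": 0.3, "snowpack": 0.0}
        out = soil_water_step(state, temp=-10.0, precip=5.0, params=p, daylen=8.0)
        assert out["snowpack"] == 0.0
        assert out["throughfall"] == pytest.approx((1 - p.k_intercept) * 5.0)

    def test_drainage_above_w_max(self, default_params):
        p = default_params
        state = {"swc_sim": p.w_max + 0.05, "snowpack": 0.0}
        out = soil_water_step(state, temp=10.0, precip=0.0, params=p, daylen=12.0)
        assert out["drainage"] == pytest.approx(p.k_drain * 0.05 * p.root_depth)

    def test_non_finite_climate_rejected(self, default_params):
        with pytest.raises(DataError):
            soil_water_step(
                {"swc_sim": 0.3, "snowpack": 0.0}, np.nan, 0.0, default_params, 12.0
            )

    def test_mass_balance_closes_on_random_trajectory(self, default_params):
        rng = np.random.default_rng(42)
        state = {"swc_sim": 0.3, "snowpack": 20.0}
        steps = []
        for _ in range(30):
            out = soil_water_step(
                state,
                temp=float(rng.normal(2, 8)),
                precip=float(rng.gamma(0.7, 6)) * (rng.random() < 0.5),
                params=default_params,
                daylen=float(rng.uniform(8, 16)),
            )
            steps.append(out)
            state = {"swc_sim": out["swc_sim"], "snowpack": out["snowpack"]}
        worst = water_balance_ledger(0.3, 20.0, steps, default_params.root_depth)
        assert worst < 1e-9


# ---------------------------------------------------------------------------
# season boundaries

class TestOnset:
    def test_zero_forcing_requirement(self):
        temp = np.full(365, -5.0)
        temp[119:] = 10.0  # first day above t_min is index 119
        p = VSParameters(t_beg=0.0)
        ones = np.ones(365)
        assert growth_onset(temp, p, ones, ones) == 119

    def test_constant_temp_at_t_min_never_starts(self, default_params):
        temp = np.full(365, default_params.t_min)
        ones = np.ones(365)
        assert growth_onset(temp, default_params, ones, ones) is None

    def test_sinusoidal_year_matches_scan_oracle(self):
        doy = np.arange(1, 366)
        temp = 2.0 + 16.0 * np.sin(2 * np.pi * (doy - 105) / 365)
        p = VSParameters(t_min=5.0, t_beg=100.0)
        gt = trapezoid_rate(temp, p.t_min, p.t_opt1, p.t_opt2, p.t_max)
        ge = np.ones(365)
        gw = np.ones(365)
        expected = scan_onset(temp, p.t_min, p.t_beg, gt, gw, ge)
        assert growth_onset(temp, p, ge, gw) == expected
        assert expected is not None

    def test_short_year_rejected(self, default_params):
        with pytest.raises(DataError):
            growth_onset(np.ones(200), default_params, np.ones(200), np.ones(200))

    def test_raising_t_beg_never_earlier(self):
        rng = np.random.default_rng(3)
        doy = np.arange(1, 366)
        temp = 2.0 + 16.0 * np.sin(2 * np.pi * (doy - 105) / 365) + rng.normal(0, 3, 365)
        ones = np.ones(365)
        prev = -1
        for t_beg in (0.0, 50.0, 150.0, 400.0, 2000.0):
            p = VSParameters(t_beg=t_beg)
            onset = growth_onset(temp, p, ones, ones)
            idx = 10_000 if onset is None else onset
            assert idx >= prev
            prev = idx


class TestCessation:
    def test_single_crossing(self):
        gr = np.concatenate([np.linspace(0, 1, 100), np.linspace(1, 0, 160)])
        end = growth_cessation(gr, 0, 0.1)
        # first post-peak day strictly below 0.1
        assert gr[end] < 0.1 and gr[end - 1] >= 0.1

    def test_v_cr_zero_ends_at_last_positive(self):
        gr = np.zeros(250)
        gr[50:201] = 0.5
        assert growth_cessation(gr, 40, 0.0) == 200

    def test_never_exceeding_threshold_flagged(self):
        gr = np.full(200, 0.02)
        assert growth_cessation(gr, 10, 0.05) is None

    def test_noisy_multiple_dips_match_scan_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(50, 250))
            base = np.sin(np.linspace(0, np.pi, n)) ** 2
            gr = np.clip(base + rng.normal(0, 0.15, n), 0, 1)
            start = int(rng.integers(0, n // 3))
            v_cr = float(rng.uniform(0.01, 0.4))
            assert growth_cessation(gr, start, v_cr) == scan_cessation(gr, start, v_cr)

    def test_raising_v_cr_never_later(self):
        rng = np.random.default_rng(9)
        gr = np.clip(np.sin(np.linspace(0, np.pi, 200)) + rng.normal(0, 0.05, 200), 0, 1)
        prev = 10_000
        for v_cr in (0.01, 0.05, 0.2, 0.5, 0.9):
            end = growth_cessation(gr, 0, v_cr)
            idx = -1 if end is None else end
            assert idx <= prev
            prev = idx


# ---------------------------------------------------------------------------
# full simulation

class TestSimulateGrowth:
    def test_gr_recomposes_from_partials(self, sim_growth):
        d = sim_growth.data
        active = d["gr"] > 0
        expected = d["g_e"] * np.minimum(d["g_t"], d["g_w"])
        assert np.allclose(d.loc[active, "gr"], expected[active])

    def test_rate_bounds_and_limiting_factor(self, sim_growth):
        d = sim_growth.data
        for col in ("g_e", "g_t", "g_w", "gr"):
            assert d[col].between(0, 1).all()
        assert (d["gr"] <= np.minimum(d["g_t"], d["g_w"]) + 1e-12).all()
        assert (d["gr"] <= d["g_e"] + 1e-12).all()
        assert d["swc_sim"].between(0, 1).all()
        assert (d["snowpack"] >= 0).all()

    def test_gr_zero_outside_season(self, sim_growth):
        for _, row in sim_growth.seasons.dropna().iterrows():
            yr = sim_growth.year(int(row["year"]))
            outside = (yr["doy"] < row["start_doy"]) | (yr["doy"] > row["end_doy"])
            assert (yr.loc[outside, "gr"] == 0).all()

    def test_non_limiting_t_and_w_give_gr_equal_ge(self):
        # mild constant summer conditions: both trapezoids sit on the plateau
        doy = np.arange(1, 366)
        # throughfall roughly balances PET so swc stays on the moisture
        # plateau all season
        clim = pd.DataFrame(
            {"year": 2001, "doy": doy, "temp": 15.0, "precip": 1.0}
        )
        p = VSParameters(t_beg=0.0, w_init=0.3, k_pet=0.05, v_cr=0.01)
        g = simulate_growth(clim, SiteConfig("X", 50.0), p)
        d = g.data
        active = d["gr"] > 0
        assert active.sum() > 100
        assert np.allclose(d.loc[active, "gr"], d.loc[active, "g_e"])
        assert (d.loc[active, "g_t"] == 1.0).all()

    def test_water_limiting_selects_g_w(self):
        doy = np.arange(1, 366)
        clim = pd.DataFrame({"year": 2001, "doy": doy, "temp": 15.0, "precip": 0.0})
        # dry year, no rain: g_w declines below g_t = 1
        p = VSParameters(t_beg=0.0, w_init=0.5, v_cr=0.001)
        g = simulate_growth(clim, SiteConfig("X", 50.0), p)
        d = g.data
        sel = (d["gr"] > 0) & (d["g_w"] < d["g_t"])
        assert sel.sum() > 10
        assert np.allclose(d.loc[sel, "gr"], (d["g_e"] * d["g_w"])[sel])

    def test_missing_days_rejected(self, sim_weather, default_params):
        broken = sim_weather.drop(index=200)
        with pytest.raises(DataError, match="missing days"):
            simulate_growth(broken, DEFAULT_SITES[0].site, default_params)

    def test_kernel_matches_reference_step(self, sim_weather, default_params):
        """In-season soil states from the compiled kernel must replay
        exactly through the reference python step."""
        site = DEFAULT_SITES[0].site
        g = simulate_growth(sim_weather, site, default_params)
        year = int(g.seasons.dropna()["year"].iloc[0])
        start, end = g.season(year)
        yr = g.year(year)
        clim = sim_weather[sim_weather["year"] == year].reset_index(drop=True)
        i0 = int(np.nonzero(yr["doy"].to_numpy() == start)[0][0])
        i1 = int(np.nonzero(yr["doy"].to_numpy() == end)[0][0])
        state = {
            "swc_sim": default_params.w_init,
            "snowpack": float(yr["snowpack"].iloc[i0 - 1]) if i0 else 0.0,
        }
        daylen = day_length(site.latitude, yr["doy"].to_numpy())
        for i in range(i0, i1 + 1):
            state = soil_water_step(
                state,
                float(clim["temp"].iloc[i]),
                float(clim["precip"].iloc[i]),
                default_params,
                float(daylen[i]),
            )
            assert state["swc_sim"] == pytest.approx(yr["swc_sim"].iloc[i], abs=1e-12)
            assert state["snowpack"] == pytest.approx(yr["snowpack"].iloc[i], abs=1e-9)


@st.composite
def valid_params(draw):
    t = sorted(
        draw(
            st.lists(
                st.floats(0.0, 30.0, allow_nan=False), min_size=4, max_size=4,
                unique=True,
            )
        )
    )
    w = sorted(
        draw(
            st.lists(
                st.floats(0.01, 1.0, allow_nan=False), min_size=4, max_size=4,
                unique=True,
            )
        )
    )
    return VSParameters(
        t_min=t[0], t_opt1=t[1], t_opt2=t[2], t_max=t[3],
        w_min=w[0], w_opt1=w[1], w_opt2=w[2], w_max=w[3],
        t_beg=draw(st.floats(0.0, 300.0)),
        v_cr=draw(st.floats(0.005, 0.5)),
        w_init=draw(st.floats(0.05, 0.95)),
        k_melt=draw(st.floats(0.0, 5.0)),
        k_pet=draw(st.floats(0.0, 0.3)),
        k_drain=draw(st.floats(0.0, 1.0)),
    )


class TestSimulationProperties:
    @given(params=valid_params(), seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_invariants_hold_for_random_parameters(self, params, seed):
        import dataclasses

        spec = dataclasses.replace(
            DEFAULT_SITES[seed % len(DEFAULT_SITES)], n_years=1
        )
        clim = gen_weather(spec, seed=seed)
        g = simulate_growth(clim, spec.site, params)
        d = g.data
        for col in ("g_e", "g_t", "g_w", "gr"):
            assert d[col].between(0, 1).all()
        assert (d["gr"] <= np.minimum(d["g_t"], d["g_w"]) + 1e-12).all()
        assert d["swc_sim"].between(0, 1).all()
        assert (d["snowpack"] >= -1e-9).all()


# ---------------------------------------------------------------------------
# annual index

class TestAnnualIndex:
    def test_identical_years_give_unit_indices(self, growth_factory):
        import pandas as pd

        frames = []
        for year in (2000, 2001):
            g = growth_factory(np.arange(100, 140), np.full(40, 0.5), year=year)
            frames.append(g.data)
        from vsxylo.core import GrowthSeries, _seasons_from_data

        data = pd.concat(frames, ignore_index=True)
        g = GrowthSeries(data, _seasons_from_data(data))
        idx = annual_index(g)
        assert np.allclose(idx, 1.0)

    def test_two_year_ratio(self, growth_factory):
        import pandas as pd

        from vsxylo.core import GrowthSeries, _seasons_from_data

        g1 = growth_factory(np.arange(100, 140), np.full(40, 0.5), year=2000)
        g2 = growth_factory(np.arange(100, 140), np.full(40, 0.25), year=2001)
        data = pd.concat([g1.data, g2.data], ignore_index=True)
        g = GrowthSeries(data, _seasons_from_data(data))
        idx = annual_index(g)
        assert idx.loc[2000] == pytest.approx(4 / 3)
        assert idx.loc[2001] == pytest.approx(2 / 3)

    def test_matches_sum_normalize_oracle(self, default_params):
        spec = DEFAULT_SITES[1]
        clim = gen_weather(spec, seed=5)
        g = simulate_growth(clim, spec.site, default_params)
        idx = annual_index(g)
        sums = np.array(
            [g.year(y)["gr"].sum() for y in g.years]
        )
        expected = sums / sums.mean()
        assert np.allclose(idx.to_numpy(), expected, atol=1e-12)
        assert idx.mean() == pytest.approx(1.0)

    def test_single_year_rejected(self, growth_factory):
        g = growth_factory(np.arange(100, 110), np.full(10, 0.5))
        with pytest.raises(DataError):
            annual_index(g)
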