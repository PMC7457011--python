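import numpy as np
import pandas as pd
import pytest

from vsxylo.core import GrowthSeries, simulate_growth
from vsxylo.params import VSParameters
from vsxylo.synthetic import DEFAULT_SITES, gen_weather


@pytest.fixture(scope="session")
def default_params():
    return VSParameters()


@pytest.fixture(scope="session")
def sim_weather():
    """Three years of weather for the warmest default site."""
    spec = DEFAULT_SITES[0]
    clim = gen_weather(spec, seed=11)
    return clim[clim["year"] <= 2004].reset_index(drop=True)


@pytest.fixture(scope="session")
def sim_growth(sim_weather, default_params):
    return simulate_growth(sim_weather, DEFAULT_SITES[0].site, default_params)


def make_growth(doys, gr, year=2000):
    """Hand-build a GrowthSeries for one year from a gr sequence."""
    doys = np.asarray(doys, dtype=int)
    gr = np.asarray(gr, dtype=float)
    data = pd.DataFrame(
        {
            "year": year,
            "doy": doys,
            "g_e": 1.0,
            "g_t": 1.0,
            "g_w": 1.0,
            "gr": gr,
            "swc_sim": 0.3,
            "snowpack": 0.0,
        }
    )
    pos = doys[gr > 0]
    seasons = pd.DataFrame(
        {
            "year": [year],
            "start_doy": [float(pos[0]) if pos.size else np.nan],
            "end_doy": [float(pos[-1]) if pos.size else np.nan],
        }
    )
    return GrowthSeries(data=data, seasons=seasons)


@pytest.fixture
def growth_factory():
    return make_growth
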