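# vsxylo

Process-based simulation of intra-annual wood formation in cold-climate
conifers, and its confrontation with microcore observations.

Dendroecologists monitoring xylogenesis count, week by week, how many
cells of a tree ring are dividing, enlarging, thickening their walls, or
mature. That monitoring is so labour-intensive that model-based
prediction of the same timings is the only way to scale it up. `vsxylo`
implements the Vaganov–Shashkin (VS) family of growth models for that
purpose: it simulates the daily tree-ring growth rate from ordinary
weather-station data, derives from it the day of year each cell starts
dividing and enlarging, and provides the full statistical machinery to
calibrate the model on ring-width chronologies and validate its
cell-level predictions against microcore data.

## The model in brief

The daily integral growth rate is

$$Gr(t) = g_E(t)\cdot\min\big(g_T(t),\, g_W(t)\big),$$

with nondimensional partial rates in [0, 1] for photoperiod
($g_E$ = day length / annual maximum), temperature ($g_T$, a trapezoid
over $T_{min} < T_{opt1} \le T_{opt2} < T_{max}$), and soil moisture
($g_W$, the analogous trapezoid on the water content of a single-layer
soil bucket with snowpack, degree-day melt, interception,
temperature–daylength evapotranspiration, and free drainage). Growth
starts when the degree-day sum above $T_{min}$ reaches $T_{beg}$ with
all three rates positive, and ends at the first post-peak day with
$Gr < V_{cr}$.

Given the annual cell production $N$, the seasonal growth sum is split
into $N$ equal quanta; cell $i$ starts enlarging when cumulative growth
reaches $i/N$ of the total and starts dividing when its predecessor
leaves the cambium. On the observation side, weekly phase counts are
GAM-smoothed to daily resolution and per-cell stage-entry days are read
off the cumulative production curves. Ring widths are detrended with
the standard 67% frequency-response cubic smoothing spline and averaged
into a biweight chronology; calibration is a seeded Latin-hypercube
search scored by Pearson r and RMSE against that chronology, retaining
the significant candidate with the smallest RMSE.

## Worked example

```python
import numpy as np
from vsxylo import VSGrowthModel, VSParameters, annual_index, simulate_growth
from vsxylo.synthetic import DEFAULT_SITES, gen_weather

spec = DEFAULT_SITES[3]                      # "DAN", 50.7°N boreal site
climate = gen_weather(spec, seed=77)         # 15 years of daily weather
truth = VSParameters()                       # generating parameters

idx = annual_index(simulate_growth(climate, spec.site, truth))
observed = idx + np.random.default_rng(78).normal(0, 0.1, len(idx))

model = VSGrowthModel(climate, spec.site, chronology=observed)
result = model.fit(seed=0, budget=200)
print(result.summary())
```

prints (abridged):

```
VS growth model fit
==============================================
site                 DAN
years                15
candidates scored    202 (budget 200, seed 0)
searched parameters  t_beg, t_opt1
----------------------------------------------
Pearson r             0.6991
p-value              0.003729
RMSE                  0.0985
RMSE < 0.3           True
retained             True
----------------------------------------------
parameters:
  t_min              4.0
  t_opt1             13.822907216681086 *
  ...
  t_beg              101.08522692584746 *
  ...
(* searched; others fixed)
```

The fit is significant (p = 0.004) and its RMSE of 0.098 sits at the
injected noise floor of 0.1 — the model explains everything except the
noise — and the forcing sum `t_beg` is recovered within one degree-day
of the generating value (100). The temperature optimum, however, lands
at 13.8 °C against a generating 10 °C: fifteen noisy annual indices
from a single site barely constrain it, because very different optima
produce nearly identical *standardized* index series. Calibrating one
parameter set jointly across several climatically distinct sites
(`vsxylo.calibration.calibrate_multi`, the package's recovery
experiment) pins `t_opt1` down to well within 2 °C. From the results
object, `result.simulate()` returns the daily growth series,
`result.seasons()` the predicted wood-formation window per year, and
`result.cell_timings({year: n_cells, ...})` the per-cell division and
enlargement days with their cambial growth rates.

The same workflow is available from the shell:

```
vsxylo synth --site DAN --seed 3 --out data/
vsxylo simulate --climate data/climate.csv --site site.yaml --out sim/
vsxylo timings  --growth sim/growth.csv --ncells data/n_cells.csv --out timings.csv
vsxylo observe  --counts data/counts.csv --anatomy data/anatomy.csv --out obs/
vsxylo chronology --widths data/ring_widths.csv --out chron.csv
vsxylo calibrate --climate data/climate.csv --site site.yaml \
                 --chronology chron.csv --seed 1 --budget 500 --out cal/
vsxylo run --seed 17 --out full_run/      # the whole pipeline at once
```

Because the original field campaign's raw data are not deposited, the
package ships a first-class synthetic-data module
(`vsxylo.synthetic`) that emulates the study conditions — five boreal
sites at 48–54° N, weekly April–October microcore sampling, rings of
15–80 tracheids, 15-year records — so every stage is testable end to
end without any download. See `docs/methods.md` for the model,
parameter defaults, and the generator's scope.

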