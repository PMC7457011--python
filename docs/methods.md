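# Methods

`vsxylo` simulates intra-annual wood formation in cold-climate conifers
with a Vaganov–Shashkin (VS) type process model, converts the simulated
daily growth curve into per-cell developmental timings, processes
microcore monitoring data into the observational counterparts of those
timings, and quantifies the agreement between the two. This note
documents the model, its parameters, the numerical choices, what the
synthetic data emulate, and the known limitations.

## The growth model

The daily integral tree-ring growth rate is

    Gr(t) = g_E(t) · min(g_T(t), g_W(t)),

where the three partial rates are nondimensional in [0, 1]:

- **Photoperiod** `g_E`: day length divided by its annual maximum at the
  site latitude. Day length uses the Spencer Fourier series for solar
  declination and a sunrise zenith of 90.833° (refraction plus the solar
  disc); polar day/night clamp to 24/0 h. The rate equals 1 at the June
  solstice at boreal latitudes.
- **Temperature** `g_T`: a trapezoid over `(t_min, t_opt1, t_opt2,
  t_max)` — zero at or below `t_min`, one on `[t_opt1, t_opt2]`, zero at
  or above `t_max`, linear between.
- **Soil moisture** `g_W`: the analogous trapezoid over `(w_min, w_opt1,
  w_opt2, w_max)` applied to the simulated volumetric soil water content
  (V/Vs). Values above `w_max` represent waterlogging and give zero.

`min(g_T, g_W)` encodes Liebig-style limitation: on any day the scarcer
of heat and water limits growth, and photoperiod scales the outcome.

**Season boundaries.** Growth initiates on the first day when (i) the
degree-day sum `Σ max(T − t_min, 0)` accumulated from 1 January reaches
`t_beg` and (ii) all three partial rates are positive. Growth ceases on
the first day *after* the within-season maximum of Gr on which Gr drops
below the critical rate `v_cr`; Gr is forced to zero afterwards and the
year is flagged degenerate (zero-length season) if Gr never exceeds
`v_cr`. No hysteresis window is applied — the first post-peak crossing
ends the season, which makes occasional short seasons possible under
noisy weather; they are retained and flagged, not dropped.

**Soil water bucket.** A single layer of depth `root_depth` (mm).
Daily, with air temperature T and precipitation P:

- T ≤ `t_snow`: P accumulates as snowpack; otherwise throughfall
  `(1 − k_intercept)·P` reaches the soil.
- Snowmelt `min(snowpack, k_melt·max(T − t_snow, 0))` enters the soil
  when the snow/melt module is active.
- Evapotranspiration `k_pet · max(T, 0) · daylength/12` mm.
- Drainage `k_drain · max(swc − w_max, 0) · root_depth` mm removes
  excess above effective saturation.
- The new content is clamped to [0, 1]; the clamping residue is
  reported so a daily mass balance closes exactly (tested to 1e−9 mm).

**Dormancy.** During dormancy the soil balance is not run: soil water is
held at the per-site winter constant `w_init` until growth onset each
year, and after cessation it is frozen at its end-of-season value for
the rest of that calendar year. Snow accumulates through dormancy and
melts by degree-days, but dormancy meltwater runs off over the frozen
soil and never enters the bucket; only snow still lying at onset is
released into the soil in-season. Two rejected alternatives are worth
recording. Carrying the end-of-season water content into the next year
makes the model fragile: one post-peak waterlogged or fully dry day ends
the season with `g_W` frozen at zero, and every later year is then
degenerate. Accumulating all winter snow without dormancy melt dumps the
entire pack into the bucket at onset and saturates it, with the same
terminal cascade. The implemented scheme keeps the winter constant-swc
behaviour of the model family, preserves a spring melt pulse in late-snow
years, and is stable over multi-decade simulations.

The simulation kernel (soil recursion and daily rates) is compiled with
numba; a pure-Python reference step (`soil_water_step`) defines the
semantics and the two are asserted equal in the test suite.

## Default parameters

| name | default | units | role |
|---|---|---|---|
| t_min, t_opt1, t_opt2, t_max | 4, 10, 20, 29 | °C | temperature trapezoid (cold-conifer envelope 4–29 °C) |
| w_min, w_opt1, w_opt2, w_max | 0.02, 0.12, 0.75, 0.90 | V/Vs | moisture trapezoid; w_max doubles as the drainage threshold |
| t_beg | 100 | °C·day | forcing sum for cambial resumption |
| v_cr | 0.05 | – | critical growth rate ending the season |
| root_depth | 400 | mm | bucket depth (shallow-rooted spruce on podzols) |
| k_intercept | 0.15 | – | canopy rain interception |
| t_snow | 0 | °C | rain/snow partition |
| k_melt | 1.5 | mm °C⁻¹ d⁻¹ | degree-day snowmelt |
| k_pet | 0.13 | mm °C⁻¹ d⁻¹ | ET coefficient (≈2.3 mm/day midsummer) |
| k_drain | 1.0 | d⁻¹ | free drainage of excess (podzol) |
| w_init | 0.30 | V/Vs | winter constant soil water |

The bucket coefficients were chosen once for hydrological realism of
wet boreal sites — summer PET roughly balancing ~2.5–3.8 mm/day
growing-season rainfall, free-draining coarse soils, and 250–400 mm
snow water equivalent — and produce growing seasons of roughly DOY
150–270 with a clear latitudinal gradient across the default sites.

## Per-cell timings from the growth curve

Given a year's Gr curve and the observed annual cell production N, the
seasonal sum `G = Σ Gr` is split into N equal quanta `q = G/N`. Cell
`i` starts enlarging on the first season day the cumulative Gr reaches
`i·q` (end-of-day resolution; ties put consecutive cells on the same
day), and starts dividing the day its predecessor enlarged — cells are
produced without overlap, and cell 1 divides on the season's first day.
The cambial cell growth rate of cell `i` is the mean Gr over its
inclusive residence window `[division_doy, enlargement_doy]`; a
`quantum` mode returning `q` itself is available since the literature is
ambiguous about which reading the original protocol used. The final
threshold `N·q` is guarded against floating-point overshoot of the
exact seasonal sum by clamping to the last season day.

## Observed timings from microcore counts

Counts of cambial/enlarging/wall-thickening/mature cells per sampling
day are pooled (averaged) across trees, then each phase is smoothed to
daily resolution with a penalized cubic smoothing spline whose penalty
is chosen by generalized cross-validation; negative fitted values are
clipped to zero. Cumulative production curves

    P_E = enlarging + wall + mature,  P_W = wall + mature,  P_M = mature

are forced nondecreasing by running maximum. Cell `j` enters a stage on
the first day the corresponding curve reaches `j − ½`. The half-cell
continuity correction exists because an integer count sits, on average,
half a cell below the latent continuous production curve between cell
entries; without it every estimated entry day is systematically late by
about half the inter-cell interval (measured: recovery of true
enlargement days within ±2 days drops from ~94% to ~76% under weekly
sampling). The correction leaves noiseless integer step curves exact and
can be set to 0 to restore the plain `≥ j` rule. Cells whose threshold
is never reached are flagged `incomplete`, never fabricated.

The observed wood-formation window starts on the first day the smoothed
cambial count exceeds its early-spring baseline (mean of the first three
grid days) by a 1-cell margin, and ends at the maturation day of the
last whole cell.

Tracheidograms are standardized by placing each radial file's cells at
relative positions `(j − ½)/n`, linearly resampling to the target cell
number, averaging across files, and lightly smoothing over position.
The observed cell growth rate is diameter divided by enlargement
duration, scaled to [0, 1] by the site-year maximum.

## Chronology

Per-tree ring widths are detrended by a Whittaker-type cubic smoothing
spline on the annual grid whose penalty is set from the standard
frequency-response criterion: amplitude 0.50 at a wavelength of
`0.67 · n` years (`λ = (2 sin(π/p))⁻⁴`). Indices are ratios
width/spline (the conifer convention), and the site chronology is the
Tukey biweight robust mean across trees (arithmetic mean optional).
Constant series detrend to exactly 1; the fit is scale-invariant.

## Calibration

Parameters are searched by seeded Latin-hypercube sampling within hard
bounds (temperature nodes confined to the 4–29 °C plausibility
envelope), each candidate simulated and scored by Pearson correlation
(two-sided p) and RMSE between simulated and observed index series. A
candidate is *retained* when p < 0.05 and its RMSE is the smallest among
significant candidates; RMSE < 0.3 is reported as a quality flag, not a
filter. An optional refinement pass polishes the best sampled
candidates with a deterministic bounded Nelder–Mead descent (two starts,
one restart each) — the sampling alone locates the optimum only to its
spacing, and the RMSE surface has flat valleys where a single simplex
can stall. `calibrate_multi` calibrates one parameter set
jointly across several sites (mean per-site RMSE, pooled correlation);
this matters because a single site's 15 noisy annual indices leave
`t_opt1` essentially unidentified (its RMSE profile is flat to within
the noise), whereas five climatically distinct sites produce a clear
minimum at the generating value. The packaged recovery experiment
searches `t_opt1` and `t_beg` jointly over the five default sites with
budget 2,000.

## Synthetic data

The generator emulates a five-site boreal latitudinal gradient
(48.2–53.8° N; mean annual temperature +1.9 to −3.4 °C; annual
precipitation 906–626 mm; mean ring size 45 down to 20 tracheids;
15-year records from 2002):

- **Weather**: an annual temperature sinusoid (minimum on DOY 27) plus
  AR(1) noise (σ = 3.5 °C, ρ = 0.75), and Bernoulli–gamma precipitation
  (wet-day probability 0.45, shape 0.7, scale matched to the annual
  total).
- **Cell production**: lognormal annual counts (CV 0.2) clipped to the
  realistic 15–80 range.
- **Differentiation schedule**: enlargement lasts 8→14 days and wall
  thickening 15→40 days from the first to last cell; diameters are the
  product of a declining rate profile (3.5→0.8 µm/day) and enlargement
  duration, giving ~30 µm earlywood and ~11 µm latewood cells.
- **Observations**: weekly (configurable 5–15 day) April–October
  sampling; phase counts by interval membership of the true timings;
  the cambial count is a dormant baseline of 4 cells plus a swelling of
  up to 5 cells proportional to the normalized daily growth rate;
  counting noise is integer-rounded Gaussian (σ = 0.5 by default)
  applied to nonzero counts and truncated at zero — an absent phase is
  unambiguous under the microscope, and adding truncated noise to zeros
  would fabricate a pre-season production floor.
- **Ring widths**: per-tree negative-exponential age trends times the
  common index signal times lognormal noise.

Everything derives from one master seed through `numpy.random`
generators, so all outputs are byte-reproducible.

What the generator does *not* emulate: spatial autocorrelation of
weather between sites, soil heterogeneity and organic-layer hydrology,
intra-seasonal variation of the cell production *rate* (cells are
produced exactly per the model's own non-overlapping protocol), missed
sampling weeks, and tree-to-tree phenological differences (all trees of
a site share one truth). Passing tests therefore demonstrate internal
consistency and statistical correctness of each stage under the stated
noise, not field validity on real microcore data.

## Numerical choices and degenerate inputs

- Calendar: DOY is 1-based; leap years keep 366 days; the solstice is
  located by day-length argmax, not a fixed date.
- Threshold crossings (model and observation sides) use ≥ at daily
  resolution with first-day tie-break, so both pipelines share one
  convention.
- Years with no onset, or where Gr never exceeds `v_cr`, get NaN season
  boundaries, zero Gr, and index 0; they are flagged, not dropped.
- Zero-variance series make Pearson r undefined — flagged NaN rather
  than raising.
- Zero-duration cells are excluded from observed growth rates and
  flagged; an all-zero duration set is an error.
- Invalid parameter combinations drawn during calibration (node order
  violated) are recorded with infinite RMSE and excluded from retention.
- Problem sizes in the packaged experiments: 1,000 random instances for
  the timing-protocol oracle check; 15 parameter draws plus 10
  one-year ledgers for the invariant suite; 20 replicates × budget
  2,000 for calibration recovery (5 replicates in the acceptance
  script); 100 site-years for the observation round trip.

## Limitations

- The end of season depends only on the integral growth rate crossing
  `v_cr`; autumn phenology is known to be the model family's weakest
  point, and the package inherits that.
- The dormancy constant-soil-water assumption misrepresents sites with
  large winter soil-moisture dynamics.
- The timing protocol assumes a constant cell-production quantum across
  the season; real cambial activity is bell-shaped, so mid-season
  timings are systematically compressed relative to a variable-rate
  protocol.
- Wall-deposition and maturation timings are *not* predicted by the
  model; they exist only on the observation side (and in the synthetic
  truth used to generate counts).
- Phloem-bound derivatives and permanently dormant cambial initials are
  not modelled.
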