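# fireregime

Fire-event delineation and fire-regime analysis for savannah ecosystems.

Savannah fire regimes are described by the long-term pattern of four
per-fire characteristics — size, ignition date (season), time since
last fire (frequency) and radiative power (intensity) — plus two
aggregates, the total number of fires and the total area burned.
`fireregime` turns gridded burned-area products (per-pixel burn dates at
500 m, MCD45A1-like) and active-fire point detections with radiative
power (MCD14ML-like) into a table of individual fire events, builds the
covariate surfaces that drive those characteristics (rainfall at two
time scales, livestock pressure from boma counts, grazer utilization
from GPS telemetry), and fits the temporal-trend and spatial driver
models. A synthetic-landscape generator with known ground truth makes
the whole pipeline runnable and testable without any data downloads.

It is written for spatial ecologists and protected-area analysts who
want a tested, reproducible implementation of this workflow rather than
a one-off script stack.

## The core algorithm and models

**Fire-event delineation.** Two burn records belong to the same fire
event iff they are connected by a chain of spatially adjacent pixels
(8-neighbour by default) whose burn dates differ pairwise by at most 5
days — a spatio-temporal flood fill, implemented as union-find over
records. Per event: size `A = n_pixels × (0.5 km)²`; ignition date
`t_ig = min_i t_i`; time since last fire
`TSLF = mean_{i: prior burn} (t_ig − t_i^prev) / 365.25` (missing when no
member pixel burned before); fire radiative power
`FRP = max` over detections inside the footprint within ±1 day of the
event's date span (missing when none match).

**Covariates.** A rainfall year runs October–September. Monthly rain is
the value in the fire's ignition month at its centroid; cumulative rain
sums from the start of the previous rainfall year (or one year earlier,
configurable) through the month before ignition. Boma (livestock
enclosure) density change is estimated per image-overlap footprint by a
Poisson GLM with log-area offset, then interpolated at 6 km by
regression kriging (management-unit trend) inside protected areas and
universal kriging (linear drift) in the buffer zone. Grazer utilization
comes from Brownian bridge movement models (BBMM) rasterized at 500 m,
reweighted by monthly Voronoi fractures, summed into monthly population
utilization distributions and rescaled to 1.

**Models.** Annual trends are Pearson correlations (df = n − 2).
Per-pixel trends are year-wise GLMs at 6 km (Gaussian for areas and
medians, Poisson for counts). Change in burnt area is a Gaussian GLM on
boma-density trend, management unit, mean and trend of annual rainfall
and baseline burnt area, with interactions, reduced by single-term
deletion LRTs at α = 0.05, followed by Tukey HSD on the management
factor and an overdispersion check for Poisson fits. Spatial drivers of
each characteristic are fitted by a latent Gaussian-Markov-random-field
regression `y = Xβ + Au + ε` with a proper CAR prior on a coarse mesh,
hyperparameters selected by a deterministic restricted-marginal-
likelihood grid search; 95% intervals assess covariate support.

## Worked example

```python
from fireregime import synthetic, fire_events, regime_summary

cfg = synthetic.LandscapeConfig(grid_nrows=50, grid_ncols=50, seed=7,
                                years=(2001, 2014))
records, truth = synthetic.generate_burn_history(cfg, 20, 10, size_sigma=1.2)
events, labels = fire_events.delineate_fires(records, cfg.grid())
print(f"{len(events)} fires delineated from {len(records)} burned pixels")

annual = regime_summary.annual_series(events, study_area_km2=625.0)
print(annual[["year", "n_fires", "area_burnt_km2", "pct_burnt",
              "top_decile_share"]].head(3).to_string(index=False))

area, frac = regime_summary.unburnt_extent(records, cfg.grid())
print(f"unburnt for the whole study: {area:.1f} km2 ({100*frac:.1f}%)")
```

prints

```
280 fires delineated from 3034 burned pixels
 year  n_fires  area_burnt_km2  pct_burnt  top_decile_share
 2001       20           39.25       6.28          0.299363
 2002       20           43.00       6.88          0.308140
 2003       20           39.50       6.32          0.259494
unburnt for the whole study: 155.0 km2 (24.8%)
```

Each row gives the year's fire count, total burnt area (km² and % of
the 625 km² landscape) and the share of that area contributed by the
largest 10% of fires. On this synthetic landscape the flood-fill stage
recovers the generator's ground-truth fire labels exactly (280 events =
280 true fires), which is the designed property the test suite checks.

The same stages are available from the shell:

```bash
fireregime simulate --out data --seed 7
fireregime delineate --burns data/burn_records.csv --detections data/detections.csv --out events.csv
fireregime run --out run1 --seed 7        # full pipeline + manifest
```

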