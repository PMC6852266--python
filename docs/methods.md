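# Methods

This note documents the models implemented in `fireregime`, the choices
made where the methodology was genuinely open, the defaults of the
synthetic-landscape generator, and what the test suite does and does
not demonstrate about real data.

## Calendars and grids

Dates are integer days since 2000-01-01; leap years are honoured by the
standard library. This makes the 5-day merging rule and rainfall-year
bookkeeping exact integer arithmetic. Day of year is 0-based (Jan 1 →
0, Dec 31 → 364, or 365 in leap years); a 1-based convention ending at
366 is only self-consistent in leap years, so the 0-based ordinal is
used and documented here.

Grids are regular, in projected metres, row 0 southernmost, with
half-open cell ownership `[x, x+Δ) × [y, y+Δ)` so boundary points are
never double-assigned. Rasters are read and written as plain-text ESRI
ASCII grids; tables as CSV; unit polygons as GeoJSON. The package
carries its own small `Grid`/`Raster` container and text raster I/O,
with shapely for all polygon work.

## Fire-event delineation

The clustering rule: records are in the same event iff connected by a
chain of spatially adjacent record pairs each differing by ≤ 5 days
(configurable), computed by union-find. Consequences and choices:

- **Connectivity** defaults to 8-neighbour, the common choice for
  burned-area mosaics; 4-neighbour is available.
- **Transitive closure**: an event's full date span may exceed 5 days.
  The alternative (global span ≤ 5) is not what a flood fill computes.
- **Repeat burns** of a pixel in different years are distinct records;
  two records at the same pixel merge only within the date tolerance.
- **Event ids** are deterministic: numbered by ignition date, then row,
  then column, so reruns are bit-identical.
- **TSLF** uses the most recent prior burn per pixel, a 365.25-day
  year, and averages only over member pixels that have burned before;
  early-period fires therefore often lack a value, an inherent censoring
  of any finite record.
- **FRP matching** tolerates ±1 day around the event's date span
  because overpass timestamps and burn-date composites are offset; the
  radiative power value is carried through in the units of the input
  (MW/km² here) without conversion.

## Rainfall covariates

A rainfall year runs October–September and is labelled by its ending
September (Oct 2005–Sep 2006 → "2006"); the labelling convention is a
package choice. Cumulative rainfall has two defensible windows — from
the start of the previous rainfall year (default) or one rainfall year
earlier (`two_rainfall_years`) — both ending at the month preceding
ignition so the monthly and cumulative covariates partition the record.
Annual-rainfall trends are per-pixel OLS (equivalently a Gaussian GLM)
of calendar-year totals against year. Static surfaces are sampled at
the fire centroid (nearest cell); footprint averaging is not used.

## Boma density

Counts per image-overlap footprint are modelled per footprint as
Poisson with log link and log-area offset (family chosen because the
data are counts; a pooled model with footprint effects is the main
alternative and per-footprint fits were chosen as the more direct
reading of "the unit of analysis"). The rate is reported on the density
scale via the delta method at the footprint's mean year, in bomas km⁻²
yr⁻¹; single-year footprints contribute a baseline only; all-zero
footprints get rate 0 and a degeneracy flag.

Interpolation is stratified: regression kriging inside protected areas
(trend = management-unit means of the point values, residuals kriged)
and universal kriging (linear drift) in the buffer zone, mosaicked by
cell-centre stratum. The variogram is exponential, fitted by weighted
least squares to a 12-bin empirical semivariogram (weights = pair
counts); a degenerate fit falls back to a nugget-only model. The
baseline (first-year density) surface is kriged from the footprint GLM
baselines by the same scheme — the construction of that surface is a
package choice. Predicted density `max(0, baseline + rate·(year−y₀))`
is clamped at zero. Holdout verification selects a seeded random 25% of
never-observed cells, excludes cells straddling the stratum boundary
(rule-based, not a hard-coded point), and reports the Pearson
correlation and the predicted:actual mean ratio uncorrected — the ratio
diagnoses bias, it does not repair it.

## Wildebeest utilization

The Brownian bridge movement model treats the path between consecutive
fixes as Brownian motion conditioned on both endpoints: at fraction `a`
through a gap of length `T` the position is Gaussian with variance
`Tσ²a(1−a) + ((1−a)²+a²)δ²`, where σ² is the motion variance (m²/s) and
δ the GPS error SD (default 20 m). σ² is estimated by leave-one-out
maximum likelihood on the odd-indexed fixes. Rasterization integrates
each bridge by 50-point midpoint quadrature in time; each node's
Gaussian is integrated **exactly** over each 500 m cell (products of
normal-CDF differences, truncated at 5σ) — point evaluation at cell
centres is badly biased when the bridge SD is below the cell size.

Unbalanced sampling across months is corrected by Voronoi-fracture
weights `w_m = min_m' n_m' / n_m` using fix counts pooled across
individuals (per-individual counts are available as an option);
fractures are cells assigned to their nearest fix, so fracture masses
tile the UD exactly. Monthly population UDs are weighted sums over
individuals, rescaled to 1, then the lowest-valued cells holding 5% of
total mass are dropped (a value-percentile mode is available) and the
surface is renormalized — renormalization is applied because downstream
covariates treat the surface as a distribution. The 3-month covariate
for a fire sums the UD value at its centroid over the ignition month
and the two prior months, missing if any month lacks a UD.

## Temporal trends

Annual correlations are Pearson product–moment tests with df = n − 2;
constant series are flagged rather than tested. Per-pixel trends at
6 km use the closed-form OLS slope for Gaussian responses (exact, and
asserted against the analytic formula in tests) and IRLS Poisson fits
for counts; cells with fewer than 3 yearly values are missing.

The area-change GLM is Gaussian with the named main effects and three
interactions (boma rate × rain mean, boma rate × baseline, rain trend ×
rain mean); the exact interaction set is exposed in the formula
argument. Backward elimination removes, per step, the removable term
with the largest LRT p-value above α = 0.05, where removability
respects marginality (no main effect leaves while its interaction
stays). The Gaussian LRT statistic is the scaled deviance difference
(Δdeviance / Pearson dispersion of the larger model) against χ²; the
null simulations in the acceptance suite confirm its size is ≈ 0.05 at
the cell counts used. Error structures are Gaussian for areas and
medians and Poisson for counts, exposed in configuration. Tukey HSD
contrasts use the fitted coefficient covariance and the studentized
range with residual df. The overdispersion check is Pearson χ²/df with
a one-sided χ² test. A domain with fewer than ~(p+5) complete cells
cannot support the full model; the fit raises and the pipeline records
the stage as skipped rather than reporting a saturated fit.

## Spatial drivers

The spatially structured regression is `y = Xβ + Au + ε` with `u` a
Gaussian Markov random field on a regular mesh (default 12 km), proper
CAR precision `τ(D − ρW)` with ρ = 0.99, and `A` the cell-membership
map. Continuous covariates are centred and scaled; cumulative rainfall
gets linear + quadratic terms (built after scaling) because fuel
accumulation can make its effect non-monotone; factors are dummy-coded.
Hyperparameters (τ, σ²) maximize the restricted marginal likelihood on
a fixed log-spaced grid anchored at the OLS residual variance — a
deterministic procedure; boundary solutions are flagged with a warning.
β and its 95% Gaussian intervals come from the GLS solve at the
optimum; with the field disabled the estimator is exactly OLS, which
tests assert to 1e-6. Responses that are strictly positive and
right-skewed (size, TSLF, FRP) are log-transformed; ignition day is
modelled linearly, not circularly — a simplification documented here.
Coverage simulations (acceptance suite) show the 95% intervals are
calibrated (pooled coverage 0.95 over 200 replicates with a smooth
spatial confounder present).

This is a deliberate likelihood-based approximation in the same model
family (latent GMRF + Gaussian fixed effects) as a fully Bayesian
SPDE/INLA fit; full posterior inference is out of scope.

## Synthetic landscape: what it emulates, and not

Defaults: 96 × 96 pixels at 500 m (48 × 48 km), years 2001–2014, eight
protected units in a 2 × 4 tiling plus a buffer ring (livestock
permitted in the communal units and buffer). Fires: 40 per year on
average (Poisson across years), truncated log-normal sizes (mean 10
pixels, log-SD 1.2 — right-skewed, so a meaningful share are single
pixels), grown by stochastic dilation with per-pixel date = seed date +
hop count capped at 5 days, seeded in a 150–270 day-of-year fire
season. Same-year fires keep a one-pixel halo and cross-year repeat
burns are months apart, so ground-truth labels are recoverable exactly
by the clustering contract — by construction. Detections: each fire is
seen with probability 0.21 (the order of real active-fire coverage);
FRP is log-normal (scale 10 MW/km², log-SD 0.8). Rainfall: bimodal
seasonality (short-rains peak November, long-rains peak April),
~900 mm/yr declining west→east at 4 mm/yr per km, optional linear
trend, multiplicative log-normal noise, on a 5 km grid. Bomas: ~2
bomas/km² base density rising toward the east and buffer, linear
density trend (default +0.05 km⁻² yr⁻¹), Poisson counts in 1–6 km
square footprints, a quarter of them in the buffer. Trajectories:
reflected Brownian motion at σ² = 50 m²/s (≈2 km daily displacement
SD), 3-h fixes, GPS error 20 m.

What passing tests therefore show: the algorithms implement their
contracts (oracle equivalence, conservation laws, exact arithmetic),
and the estimators recover known parameters under the stated noise
models. What they do not show: performance under real-data pathologies
— cloud-gap missingness in burn dates, spatially correlated detection
failure, boma miscounts, irregular fix schedules, non-Brownian movement
— none of which the generator emulates beyond uniform detection
probability.

## Problem sizes and numerics

The default pipeline scale (96 × 96 grid, 64 coarse cells, ~550 fires,
12 UD months) runs in about a minute on one CPU; tests use smaller
grids chosen so every stage still satisfies its preconditions (the
drivers stage needs ≥ 10 observations per design column; the
area-change model needs more cells than parameters plus five).
Simulation-based checks use 200 replicates for interval coverage,
1,000 for LRT size, and 100 for power, with seeds fixed in the tests.
Numerical tie-breaks: kriging systems fall back to least squares if
singular; zero-variance covariates are dropped with a warning; medians
of even counts use the midpoint; all-missing medians are missing, not
zero.
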