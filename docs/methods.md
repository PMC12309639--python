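# Methods

`ridge2reef` implements a land–sea ("ridge-to-reef") conservation
prioritization chain for a coastal seascape threatened by storm-driven
sediment runoff. The chain has five scientific stages; each is described
below together with the assumptions, defaults, and numerical choices
that matter.

## 1. Storm-event sediment yield and routing (`hydro`)

Runoff from an extreme rainfall event is computed per DEM cell with the
SCS curve-number method: retention `S_ret = 25400/CN − 254` mm and
runoff depth `Q = (P − 0.2 S_ret)² / (P + 0.8 S_ret)` for rainfall `P`
above the initial abstraction, else zero. The per-cell sediment yield is
the storm-event modified universal soil loss equation (MUSLE)

    S = a (Q_vol · q_p)^b · K · C · P_practice · LS,

with runoff volume `Q_vol` (m³), peak flow `q_p` (m³/s), soil
erodibility `K`, cover-management factor `C`, supporting-practice factor
`P_practice`, and the RUSLE topographic factor `LS`. Defaults are the
standard metric coefficients `a = 11.8`, `b = 0.56`; both are
configurable because regional recalibrations of MUSLE exist. Yields are
treated as *relative*: only ratios between cells and watersheds carry
meaning, which is all the downstream dispersion model uses.

Peak flow uses a uniform-release proxy — the cell's runoff volume spread
over a configurable storm duration (default 24 h). No hydrograph shape
is modelled; the proxy is linear in runoff and therefore preserves the
relative ordering of cells, which is the property the relative yields
require.

Routing is D8 over a priority-flood depression-filled DEM. Filling
imposes a minimal gradient (1e-6 × cell size per step) across flats so
steepest descent is defined everywhere and the flow graph is acyclic.
Ties between equally steep neighbors break on a fixed clockwise order
starting east, making all routing deterministic. The DEM's no-data mask
marks sea; a cell whose steepest descent leaves the land (sea or grid
edge) is an outlet. Watersheds are the sets of cells draining to each
outlet; they partition the land, and pour-point loads are exact
watershed sums of cell yields (no in-stream deposition), so total load
always equals total yield.

The `LS` slope length is the *longest* upstream flow-path length
entering a cell (one cell length for headwater cells); slope is taken
along the steepest descent. The slope-length exponent follows the
standard slope-class table (0.5 above 5% gradient, then 0.4/0.3/0.2).

## 2. Plume dispersion (`plume`)

Each river-mouth load `β_j` spreads over the sea as a power law,
`z_ij = β_j d_ij^α`, summed over sources; the coral covariate is
`log(Σ_j z_ij)` (natural log — the base only shifts the covariate and is
absorbed by the spline). The dispersion exponent defaults to `α = −2.3`,
a value calibrated for sediment plumes along high-island fringing-reef
coasts. Distances are in kilometres, euclidean by default (the model
deliberately excludes currents, wind and bathymetry; it is a screening
model for data-poor regions); an over-water metric (shortest 8-connected
path through sea cells, Dijkstra) is available when land barriers
matter. All distances are floored at 0.5 km — half a planning-unit
side — to remove the `d → 0` singularity at the river mouth itself.

## 3. Coral condition model (`coral`)

Hard-coral cover at surveyed sites is modelled as binomial counts with

    logit(p) = f(log TSS) + u_site,

where `f` is a penalized cubic regression spline (10 basis functions by
default, knots at covariate quantiles, *exact* integrated
second-derivative penalty computed by per-span Gauss–Legendre) and the
site intercepts `u` are ridge-penalized — the standard representation of
a Gaussian random intercept as a quadratic penalty. For a single smooth
of one covariate this penalized-spline construction behaves like the
thin-plate version while staying self-contained.

Fitting is penalized IRLS. The curvature penalty λ is selected on a
9-point log grid (scaled to the data's curvature scale) by GCV,
`n·deviance/(n − edf)²`. The site ridge co-adapts inside each fit by the
variance-component fixed point `σ̂²_u = ‖û‖²/edf_u` with
`λ_site = 1/σ̂²_u`, where `edf_u = q − λ_site·tr(C_uu)` and `C` is the
penalized information inverse — the usual REML-type update. The reported
`site_effect_sd` is `σ̂_u`.

With one pooled observation per site (3 × 100 points by default), the
site intercept is an observation-level random effect, i.e. exactly the
lognormal-binomial overdispersion model; the overdispersion check
(Pearson χ² over residual df, "ok" within [0.7, 1.4]) is therefore a
*conditional* check and calibrates tightly around 1 for binomial data
while inflating strongly (ratios ≳ 1.5 at intra-class ρ = 0.1) for
beta-binomial alternatives. A residual semivariogram of deviance
residuals screens for spatial autocorrelation.

Uncertainty propagates by empirical-Bayes posterior simulation: draws
from `N(β̂, (XᵀWX + S_λ)⁻¹)`. The probability a cell's coral is in
good condition (cover > 0.30, configurable) is the fraction of draws
whose predicted cover at the cell's log-TSS exceeds the threshold, with
the site effect at its population mean of zero — per-cell site effects
do not exist away from the survey sites, so predictions are
population-level; this is flagged as a modelling choice. The spline is
clamped at the surveyed covariate range: cells more turbid (or clearer)
than any survey site take the boundary value rather than an
extrapolation.

## 4. Reserve selection (`prioritize`)

The minimum-set problem selects planning units to minimize

    Σ c_i x_i + BLM·boundary(x) + Σ_j SPF_j · shortfall_j.

Deterministic features have `shortfall_j = max(0, T_j − held_j)`.
Probabilistic features (the coral feature in the cyclone scenario) treat
each selected unit's contribution as `a_ij · B_i` with independent
`B_i ~ Bernoulli(p_i)`, `p_i` the unit's good-condition probability, and
require `P(held ≥ T_j) ≥ P_j` (certainty 0.9 by default). The
attainment probability uses the normal approximation
`1 − Φ((T_j − μ)/σ)` with `μ = Σ a_ij p_i`, `σ² = Σ a²_ij p_i(1 − p_i)`;
its shortfall is `max(0, P_j − prob)·T_j`, the `T_j` scaling putting it
in the same amount units as deterministic shortfalls. Two deliberate
refinements:

- When σ = 0 (every selected unit certain) the probabilistic shortfall
  falls back to the deterministic `max(0, T_j − μ)`. This makes the
  probabilistic mode collapse *exactly* onto the deterministic mode when
  all `p_i = 1` (paired-seed runs produce identical trajectories) and
  gives the annealer a gradient where a step function would stall it.
- The normal approximation carries no continuity correction (its closed
  form is part of the model definition). On equal-amount units the held
  amount is lattice-valued and the approximation can err by more than
  0.05 for targets near the middle of the distribution; in the planning
  regime — targets in the attainable tail, where certainty constraints
  of 0.9 operate — the error stays well below 0.05, and an exact
  Poisson-binomial oracle is shipped for verification.

Independence of unit outcomes is assumed; spatially correlated cyclone
impacts are out of scope.

The solver is simulated annealing over single-unit flips with
incremental objective updates (the inner loop is JIT-compiled),
geometric cooling, and a greedy improvement pass to a local optimum.
The start temperature ("auto") is the 90th percentile of |Δobjective|
over random flips. Cooling defaults to "auto": the per-iteration factor
is chosen so the temperature decays to 1e-4 of its start *over the whole
run* — a fixed per-iteration factor freezes long runs in their first few
percent and measurably degrades final objectives. Defaults: 300,000
iterations and 100 restarts (seeds = base seed + run index), giving the
best solution and per-unit selection frequencies. On 12-unit instances
the best-of-100 matches the exhaustive 2¹²-enumeration optimum in ≥ 90%
of instances.

SPF defaults to `10 × max(cost) / mean positive amount` per feature:
scaling by the *maximum* unit cost guarantees that buying even the most
expensive unit is preferred to leaving a comparable shortfall. (Scaling
by the mean cost fails on kernel-density cost surfaces, where the units
carrying a feature can cost orders of magnitude more than the average
unit — targets on expensive coastal units then go unmet.) BLM defaults
to 0; raise it gradually (0.01–1 × mean unit cost per km of boundary)
until the solution is as compact as the planning context requires.

## 5. Scenario comparison (`report`)

Two scenarios are compared: *baseline* (all features deterministic) and
*cyclone risk* (coral probabilistic with certainty 0.9). Because a
selection meeting the probabilistic coral constraint necessarily holds
the full target amount, every cyclone-feasible solution is
baseline-feasible; at true optima the cyclone cost therefore bounds the
baseline cost from above, and the package reproduces that directional
trade-off (slightly larger, costlier cyclone designs) on default
synthetic worlds. Overlap statistics share a single intersection with
two denominators; high-priority area uses a strict `> 0.8` selection
frequency threshold. All areas come from unit geometry (cells × cell
area), never raster resampling.

## The synthetic generator (`synth`)

The generator builds the study system the pipeline is tested on:

- **Terrain**: radial island bumps plus a smoothed Gaussian random
  field, thresholded to a configurable land fraction (0.22) with the
  largest connected components kept and a two-cell sea ring forced at
  the region edge. Default 64 × 64 cells at 1 km — the planning grid
  and terrain grid coincide, so every sea cell is a 1 × 1 km planning
  unit. (A real deployment would use a much finer DEM, ~90 m, for the
  hydrology; the 1-km desk scale keeps every stage's behavior
  observable in seconds without changing any algorithm.)
- **Land cover**: four classes from an elevation-plus-noise suitability
  index: forest (C = 0.003, CN = 58), grassland (0.05/69), agriculture
  (0.35/78), urban (0.01/92); K from a clipped random field
  (0.02–0.4); storm rainfall 300 mm ± 25% smooth spatial variation —
  an extreme-cyclone event depth.
- **Marine features**: a coral reef arc 3–7 cells offshore (patchy,
  densest mid-band), mangrove hugging the coastline, seagrass patches
  inshore, and three large turtle-ground patches overlapping
  seagrass/coral — the qualitative co-location that drives shared
  high-priority areas.
- **Cost**: coastal towns (5, total population 60,000) with a quartic
  (biweight) kernel density, radius 10 cells; planning-unit cost is
  density × cell area. Problem assembly adds a floor of 2% of the mean
  positive cost so far-offshore units are never exactly free — free
  units would wander in and out of solutions without consequence and
  wreck area comparisons.
- **Surveys**: 72 sites × 3 transects × 100 point-intercept points,
  sites stratified one-per-stratum over the log-TSS range of
  coral-bearing cells (so the covariate is identified across its
  range), binomial counts from the truth curve plus
  `N(0, 0.5²)` site effects.
- **Truth**: `logit(cover) = 6.0 − 0.78·logTSS − 0.2·sin(logTSS/1.5)`,
  a smooth monotone-decreasing curve calibrated once to the default
  landscape's relative TSS scale so cover sweeps from roughly 70% at
  the clearest reefs to under 10% at the most turbid, crossing the 30%
  good-condition threshold mid-range. The TSS units are relative, so
  this calibration is part of the scenario definition, not a fit.

What the generator does *not* emulate: real coastline geometry, tides
and bathymetry, multi-island realism, spatially correlated survey
error, and any hydrodynamic plume behavior. Passing tests therefore
demonstrate the *methods* recover a known data-generating process of
the assumed form; they do not validate the form against real reef data.

## Reproducibility and problem sizes

Every random stage draws from `numpy` `SeedSequence` streams spawned
from a single base seed; the annealing kernel seeds its own generator
per restart. Identical configs reproduce bit-identical artifacts (the
pipeline manifest records SHA-256 checksums of every file). The test
suite and the acceptance script use 64 × 64 worlds (~3,700 planning
units, ~400 land cells), 16 × 16 DEMs against brute-force oracles,
12-unit problems against exhaustive enumeration, 100-replicate
parametric bootstraps for the dispersion check, and 1,000 posterior
draws for condition surfaces; a full two-scenario pipeline runs in
roughly 20 s on one core.

## Known limitations

- Selection frequencies are diffuse on the synthetic worlds: large
  pools of near-identical cheap offshore units are interchangeable, so
  few units exceed the 80% frequency threshold — a real cost surface
  with more heterogeneity concentrates frequencies.
- The annealer's best-of-ensemble is a heuristic optimum; paired
  scenario comparisons inherit a small solver noise floor (~1% of
  objective at default settings).
- The overdispersion check is conditional on the site effects and so
  cannot detect overdispersion the site intercepts absorb; the
  beta-binomial inflation it does detect operates through the refit's
  residual structure.
- The curve-number and MUSLE coefficient defaults are literature
  standards, not calibrated to any specific region; all are exposed in
  the config.
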