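# Methods

`mangrovemove` analyses GPS telemetry of tigers living in a mangrove
archipelago — a mosaic of forested islands separated by tidal water channels
— and ships a synthetic landscape-and-trajectory generator so that every
estimator can be exercised against a known truth. This note records the
models, the defaults and why they were chosen, the numerical choices, and
what the simulation results do and do not establish.

## Coordinate and time conventions

All coordinates are planar, in meters, with no geographic CRS; distance is
Euclidean. Inputs in geographic coordinates must be projected before use.
Timestamps are UTC; the local civil clock (day boundaries, the 06:00/18:00
day/night split, the hourly activity clock) is UTC plus a configurable
offset, +05:30 by default. Day boundaries fall on local civil midnight; the
source studies do not state a day convention, and local midnight is the
least surprising choice.

## Synthetic landscapes

A landscape is a five-class habitat raster plus a set of width-attributed
channel features. The default class mix is that of a large mangrove tiger
reserve: Water 41.5 %, *Phoenix* thicket 36.9 %, *Ceriops* shrub 11.9 %,
barren flats 5.2 %, *Avicennia–Sonneratia* silt banks 4.5 % (those field
map percentages sum to 100.03 and are normalized here). Channels are straight
north–south corridors of constant width, drawn log-uniform within the
spec's width range (default 30–2500 m) and placed without overlap; their
edges are snapped to the raster grid so that the vector features and the
rasterized Water cells coincide exactly — otherwise bank-walking animals
produce sliver "crossings" where the two representations disagree. Channel
widths are therefore quantized to the cell size (default 50 m). The land
classes fill the remaining cells by thresholding a Gaussian-smoothed random
surface (patch scale 300 m) in order of notional elevation — residual open
water lowest, then silt banks, barren flats, *Ceriops*, and *Phoenix* on the
highest ground — with class counts chosen exactly, so realized fractions
match the recipe to within one cell per class (and always within the
contracted ±2 percentage points).

## Synthetic tigers

Movement is a biased correlated random walk evaluated at the fix schedule
(default: one position per hour for 90 days). At each step:

- heading is wrapped-normal around a blend of the previous heading and the
  direction to the home center; `attraction_strength` (default 0.5) weights
  the homeward pull, `turning_concentration` κ (default 1) sets the
  wrapped-normal precision (κ = 0 gives uniform headings);
- step length is `step_scale` × an hour-of-day activity multiplier ×
  Uniform(0.5, 1.5). The default activity profile peaks at 05:00–10:00 local
  (maximum near 07:00) with a midday lull, normalized to mean 1, matching
  the dawn-active pattern of mangrove tigers. `step_scale` = 193 m is tuned
  once so the default world travels ≈ 4.6 km per day over 200 days, the
  mean daily distance reported for these tigers in the field;
- a proposed endpoint in class *c* is accepted with probability
  `weight[c] / max(weight)` — a Metropolis-style rule whose stationary
  distribution is proportional to habitat weight × availability — and a
  step that fully spans channels of total width *w* is further accepted with
  probability `2^(−w / crossing_halfwidth)` (default half-width 150 m, at
  which field tigers' mean crossed width ≈ 54 m and channels beyond
  ≈ 400 m are rarely crossed). Rejected proposals are redrawn up to 50
  times; if all fail the animal stays put for that interval.

Default habitat weights are deliberately distinct, ranked
*Avicennia–Sonneratia* (8) > *Phoenix* (4) > *Ceriops* (2) > Barren (1) >
Water (0.5): the generator's job in recovery experiments is to plant an
unambiguous preference order, and field studies report exactly
this order. Scheduled fixes drop out independently with probability
1 − `fix_success_prob` (default success 0.666, the field-observed acquisition
rate). With the default 1-h schedule this yields ≈ 16 valid fixes per day,
so most days clear the 12-fix usability threshold; field collars
sampled every 1–3 h.

The truth record carries the full path, per-day distances, per-channel
crossing counts and class occupancy, so downstream estimates can be checked
against what actually happened.

## Home ranges

- **MCP.** The minimum convex polygon at level *p* removes the
  ⌈(1 − p/100)·n⌉ fixes farthest from the arithmetic centroid before hull
  construction (shapely hull; an independent qhull oracle in the tests).
  Fewer than three input fixes is an error; three or more degenerate
  (identical/collinear) fixes give a flagged zero-area result.
- **Fixed kernel.** The utilization distribution is the mean of circular
  bivariate Gaussian kernels of standard deviation *h* (the smoothing
  parameter, default 1000 m), computed by binning fixes to a grid (default
  cell h/10, padding 4h) and Gaussian-filtering, then renormalizing to unit
  mass. Isopleths are smallest-area superlevel sets: cells are accumulated
  in decreasing density order until the target mass is reached — exact on
  the grid, no contour interpolation. A single-fix UD reproduces the
  closed-form isopleth areas (−2 ln(1 − p) π h²) within 2 % at cell = h/10.
- **Water masking.** Channels wider than 1 km are non-habitat: their
  geometry is differenced out of home-range polygons (strictly greater than
  the threshold; a 900 m channel is habitat matrix).
- **Asymptote.** Areas are computed on the first 50, 100, … fixes; the
  asymptote is the first sample size whose gain over the next increment
  falls below 5 % of the current area.
- **Core area.** The core isopleth is the level maximizing the second
  forward difference of area versus level (the sharpest upward bend of the
  area curve), ties broken toward the higher level; a strictly linear
  profile has no core. The detector is invariant to rescaling all areas.
  Note that for utilization distributions whose background is itself
  heavy-tailed (e.g. a wide Gaussian), the curvature of the area curve keeps
  growing toward the 95 % level and the detected "core" sits high; the
  detector's calibration test therefore uses a tight-core-plus-uniform
  background construction, where the bend is unambiguously at the planted
  mass boundary.
- **Density.** Treating mean territorial core areas as exclusive, the
  number of residents per sex is land area / mean core (rounded half-up),
  with an SE range from land / (mean ± SE); density per 100 km² is
  100 × (n_f + n_m) / land to one decimal. This reproduces the field
  worked example (1645 km², cores 34.81 ± 7.26 and 58.27 ± 25.51 →
  47 (39–60) females, 28 (20–50) males, 4.6 (3.6–6.7) per 100 km²).

## Movement metrics

Daily distance sums consecutive-fix step lengths within a usable
(≥ 12 fixes) local day. The activity profile assigns each step's speed
(km/h) to the local hour of the step start. Steps above 10 km/h are flagged
but never dropped (collared tigers show genuine >5 km/h bursts). Dates are
spring tide inside the 8-day window [syzygy − 3, syzygy + 4] around each
new/full moon and neap otherwise; the synthetic syzygy calendar spaces
syzygies at the mean half-synodic interval (14.765 d). The movement model
is a linear mixed model on log half-day distance with fixed effects for
daytime and tide phase and a random intercept per animal (statsmodels
MixedLM, REML; the default optimizer — L-BFGS silently collapses the
intercept on these data). Zero distances are floored at half the minimum
positive distance before the log. With a single animal the model falls back
to OLS with a warning. The half-day response (rather than whole days) is
what makes a day/night fixed effect estimable.

## Channel crossings and the barrier test

Crossing records are maximal positive-length intersections of
consecutive-fix segments with channel geometries; re-entering a channel
later in the day counts again, grazing point contacts do not. Availability
comes from null trajectories matched to each observed daily path: same
start, same step count, lengths uniform within the day's [min, max] step
length, uniform headings, and every node constrained to the study polygon
and to land. **Nodes are rejection-resampled one at a time.** Discarding
whole trajectories instead (the field procedure) weights path space by
the product of per-step land fractions, which systematically under-visits
banks — and does so width-differentially, because wide channels carve out
more rejection probability. In simulation that whole-path rule behaved like
an implicit crossing reluctance of roughly 200 m half-width: it inflated
the null-hypothesis rejection rate to ~0.9 and *canceled* genuine avoidance
signals. Per-node resampling keeps the null walk's law identical to an
unconstrained walk conditioned step by step on land, which is also the law
of the simulator's own non-reluctant walk.

Observed and available crossings are tallied into half-open width bins
(50 m to 1000 m, then 500 m), expected counts are availability proportions
scaled to the observed total, adjacent bins are merged until every expected
count reaches 1, and χ² = Σ(obs − exp)²/exp with df = bins − 1.

**Calibration caveat.** Even with per-node nulls and a null-consistent
simulated walk, the test rejects a true null far above its nominal 5 %
(measured ≈ 40–50 % at α = 0.05 over 100 replicates). Two irreducible
causes: crossings of the same channel cluster strongly along a path
(overdispersion relative to the multinomial the χ² assumes), and the
expected proportions are estimated from only five equally clustered null
paths per observed path. The corresponding acceptance check is therefore
red by design of the statistic, not by implementation defect: no
parameterization of the world meets nominal size without replacing the
statistic itself. The test's *power* is excellent — a 200 m half-width
reluctance is detected in ≈ 100 % of replicates at ~200 observed days — and
since the field use of the test is to demonstrate avoidance (where
anti-conservatism only adds to an enormous true signal), the qualitative
conclusion survives; its printed p-value should not be read at face value.

The calibration/power experiment world is an isotropic land-only walk
(uniform land weights, no home attraction, flat activity, complete 2-h
schedule) on a channel-dense landscape calibrated so a resident crosses
≈ 5 channels per day, the rate observed in the field.

## Habitat selection

Use is the proportion of fixes per class; availability is the class
composition of the animal's 95 % fixed-kernel range (computed on the
habitat raster's grid so the isopleth mask indexes classes directly).
Compositional analysis forms per-animal differences d = ln(u/u_ref) −
ln(a/a_ref) against a reference class (Water by default — the statistic and
ranking are provably and test-verifiably invariant to that choice), tests
mean(d) = 0 via Wilks' Λ = det(centered SSCP)/det(raw SSCP), and reports
χ² = −N ln Λ on D − 1 df plus a pairwise t-matrix whose win counts order
the classes. Zero use proportions are replaced by 0.01 and renormalized
(the standard fix for the log-ratio transform); zero *availability* — which
can genuinely occur when a small simulated home range misses a rare class —
is substituted the same way with a warning rather than refused. With
N ≤ D − 1 animals the cross-products are singular and only the ranking is
returned, with a warning. An optional sign-flip permutation p-value is
available for small samples. Ivlev electivity E = (u − a)/(u + a) ∈ [−1, 1]
is reported per animal and class for plotting; it is antisymmetric in
(u, a) and NaN where u + a = 0.

## Pipeline

`run_pipeline` (or `mangrovemove run`) chains simulate → validate → home
range → movement → crossings → habitat → density from one YAML/dict
configuration. A single global seed spawns independent substreams per
stochastic stage, so a run is byte-reproducible and stages can be re-run in
isolation. Each stage writes its outputs (CSV, GeoJSON, ESRI ASCII grid,
JSON, PNG) before the next starts; failures halt with the stage name,
keeping partial outputs. The default demo is six tigers (three of each sex;
females with stronger home-site attraction and hence smaller ranges) for 60
days on a 20 km landscape. Where null-path generation for a day exhausts
its proposal budget the pipeline keeps the paths it got and reports
requested vs. accepted counts, mirroring field analyses in which a fraction
of random trajectories cannot be placed.

## What the generator does not emulate

No tidal inundation dynamics (tide phase influences nothing in the
simulator, which is exactly what the movement model's null calibration
requires); no territoriality or interaction between animals; no GPS
position error; channels are straight, constant-width and axis-aligned;
fix dropout is independent rather than habitat- or posture-dependent. A
green recovery test therefore establishes that the estimator recovers the
model's truth under these idealizations, not that field data meet them.

## Known limitations

- The raw-count barrier χ² is anti-conservative under crossing clustering
  (measured, documented above); interpret its p-values qualitatively.
- The half-width of the crossing-reluctance rule is recovered from the
  fitted width decay only to within a factor of ~1.5 at 500 tracking days:
  reluctance feeds back on occupancy (a tiger that declines a crossing
  lingers at the bank, re-encountering exactly the channels it avoids),
  which flattens or steepens the apparent decay per channel.
- Core-isopleth detection depends on the shape of the area-vs-level curve;
  for heavy-tailed utilization distributions the maximum-curvature rule
  saturates near the top levels.
- The exclusive-core density extrapolation inherits all the assumptions of
  the field method: cores tile land without overlap or vacancy, and the
  sex-specific means are representative.
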