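# mangrovemove

Home-range, movement and habitat-selection analysis for tiger telemetry in
mangrove island landscapes — with a synthetic landscape-and-trajectory
generator so the whole pipeline is testable against known ground truth.

Mangrove deltas are mosaics of forested islands separated by tidal water
channels. For a large territorial carnivore tracked by GPS collar there,
the questions are: how big are home ranges and their intensively used
cores; how far and when do animals move; do wide channels act as movement
barriers; and which habitats are preferred relative to availability?
`mangrovemove` implements the standard estimator chain for those questions:

- **Home range** — minimum convex polygon (95 % MCP trims the fixes
  farthest from the centroid before hull construction) and fixed-kernel
  utilization distributions (circular Gaussian kernels, smoothing parameter
  h = 1000 m), with 5–95 % isopleths computed as exact grid superlevel
  sets, area-vs-fixes asymptote curves, a core area at the inflection of
  the area-vs-isopleth curve, and masking of water channels wider than
  1 km as non-habitat.
- **Density** — treating mean territorial core areas as exclusive, the
  number of residents each sex's core tiles into the land area, and the
  implied density per 100 km² with SE ranges.
- **Movement** — daily travel distance over ≥ 12-fix days, an hourly
  activity clock (speed by local hour), and a linear mixed model of log
  half-day distance on day/night (06:00–18:00 local) and spring/neap tide
  phase (8-day windows around new/full moon), with a random intercept per
  animal.
- **Barrier test** — channel crossings detected as segment–channel
  intersections along daily paths, availability from random null
  trajectories matched to each path (same step count, step lengths within
  the observed range, land-only nodes inside a study polygon), counts
  binned by channel width (50 m bins to 1 km, then 500 m) and compared by
  chi-square. See `docs/methods.md` for a measured calibration caveat on
  this classical statistic.
- **Habitat selection** — use (fixes per class) vs availability (class
  composition of the 95 % kernel range), compositional analysis (Wilks' Λ,
  χ² = −N ln Λ on D − 1 df, pairwise log-ratio t-matrix and preference
  ranking) and Ivlev electivity E = (u − a)/(u + a) per animal for
  plotting.
- **Synthetic worlds** — habitat rasters with the class mix of a mangrove
  tiger reserve (41.5 % water, 36.9 % *Phoenix*, …), straight
  constant-width channels (30–2500 m), and biased correlated-random-walk
  tigers with a dawn activity peak, ranked habitat weights, ~4.6 km/day
  travel, 66.6 % fix acquisition, and an explicit width-dependent crossing
  reluctance `2^(−w/halfwidth)` — with the realized truth (daily distances,
  per-channel crossings, class occupancy) recorded for downstream checks.

Formats: fixes as CSV (`animal_id, timestamp, x_m, y_m, status`), habitat
rasters as ESRI ASCII grids, channels and polygons as GeoJSON (`width_m`
property), reports as JSON + Markdown. All coordinates are projected
meters; local time is UTC+05:30 by default.

## Worked example

Run the bundled six-tiger demo (three of each sex, 60 days on a 20 km
synthetic landscape) and read the report:

```sh
mangrovemove run --seed 1 --out demo_run
cat demo_run/report.md
```

which prints:

```
# mangrovemove run report

- seed: 1
- animals: 6
- fix acquisition success: 0.668
- core isopleth level: 90.0%
- density per 100 km2: 9.0
- mean daily distance (per day): 3.90 km
- crossing test: chi2=2481.83, df=1, p=0
- habitat ranking: AvicenniaSonneratia > Phoenix > Ceriops > Barren > Water
```

Reading the numbers: two thirds of scheduled fixes succeeded (the collars
were configured with 66.6 % acquisition); the area-vs-isopleth curve of the
pooled kernel ranges bends hardest at the 90 % level, so that isopleth is
taken as the territorial core; tiling the landscape's land area with the
sex-specific mean core areas accommodates a density of 9.0 tigers per
100 km² (the demo landscape is small, so ranges press against its edges);
the tigers walked ~3.9 km per day; the chi-square rejects the hypothesis
that channels are crossed in proportion to their availability — these
simulated tigers carry a 150 m crossing half-width, so wide channels are
genuinely avoided, and with only a handful of crossable channel widths on
this small landscape the merged table retains a single degree of freedom;
and compositional analysis recovers the planted habitat preference order
exactly. Per-animal tables (`home_ranges.csv`,
`daily_distance.csv`, `use_availability.csv`, `ivlev.csv`), the crossing
width bins, an activity histogram and an Ivlev bar chart are written next
to the report.

The same stages are available piecewise (`mangrovemove validate | simulate
| homerange | movement | crossings | habitat`) and as library functions
(`mangrovemove.home_range.compute_fixed_kernel_ud`, … — see
`docs/methods.md` for the full model documentation).

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from scratch
— generating a synthetic landscape and tiger trajectories, then executing
the full home-range / movement / crossing / habitat / density pipeline —
and writes its results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The `--seed` argument drives every source of randomness in the run.
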