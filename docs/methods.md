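# Methods

This note documents the models, parameter choices and numerical decisions
behind seatrack, and what the synthetic-data validation does and does not
demonstrate about real telemetry.

## Coordinates, time and formats

All coordinates are planar (UTM-style) meters; the package performs no
geodetic math. An optional ingest hook (`read_fixes(..., xy_transform=...)`)
accepts a user-supplied callable for projecting raw lon/lat, since distances,
speeds and areas are only meaningful on a projected plane. Timestamps carry a
fixed local UTC offset per deployment, and all day/night, duty-cycle and
calendar logic uses that local wall clock (the diurnal boundary is
06:00–18:00 local). Fix tables are headered CSV with configurable column
names; polygons are GeoJSON; rasters are ESRI ASCII grids. All formats are
plain text, so runs are diffable and portable.

## QC filtering

Species-specific chains reflect the different tag technologies:

* **Dugong tags** (GPS with Quick Fix Pseudoranging fallback): class gating
  retains `GPS_SUCCEEDED`, `QFP_RESOLVED` and `QFP_UNCERTAIN`
  (accuracy ≤ 75 m; unresolved QFP is only good to several hundred meters),
  then over-speed removal at V_max = 10 km h⁻¹, then the 30 m inland rule
  (30 m is the error of the most precise QFP tier).
* **Turtle tags** (fast-acquisition GPS): the manufacturer quality filter
  first (residual error > 30 — strictly greater, so 30 is retained — or
  fewer than 4 uplinks; a missing residual fails and is logged), then the
  data-driven V_max/loop-trip filter (V_max = 9.9, V_lp = 2.0 km h⁻¹), then
  the inland rule with an optional basking buffer, since turtles can
  legitimately strand on tidal flats between fixes.

Decisions where the verbal rules needed operationalizing:

* **Which fix of an over-speed pair to drop.** The forward pass anchors on
  the last retained fix and drops the later offender, iterating to a fixed
  point. This preserves continuity from a trusted anchor; comparison against
  the immediate raw predecessor is available via
  `FilterConfig(compare_to_raw_predecessor=True)`.
* **"Acute"** means strictly < 90°; a right-angle vertex is retained.
* **Loop-trip clause (c)** is read as speed *into* or *out of* the focal fix
  exceeding V_lp.
* Every filter returns the removed indices; removed + retained = input is
  asserted at every stage so no fix is lost silently. All filters are
  idempotent, order-preserving subset operations.

Tag-detachment flagging looks for three signatures — a metronomic run of
GPS-succeeded fixes at exactly the nominal schedule, prolonged
constant-heading constant-speed drift, and a stationary signal over several
days — and returns the index where the first signature begins. It only
flags; truncation is a user decision because a resting animal can mimic a
detached tag.

## Duty-cycle standardization

Windows are 3 h, half-open, anchored at local midnight so they align with
the 06:00/18:00 diurnal boundaries and are reproducible across runs (the
anchoring is a package decision; any fixed anchor gives a valid partition).
The best fix per window is chosen lexicographically: most satellite uplinks,
then lowest residual error (turtle tags) or lowest PDOP (dugong tags) with
missing values ranking last, then smallest distance to the *median member
timestamp* (not the window midpoint — switchable in
`select_best_fix`), then earliest. Thinning never alters coordinates.

## Foraging segmentation

The 45° rule: step i is directed when the bearing of (i → i+1) deviates less
than 45° (strict) from the bearing of (i−1 → i). Days are local calendar
days; a day is non-directed when fewer than half of its steps are directed
(a day exactly at the threshold counts as directed). Foraging onset is the
first day of a run of ≥ 3 consecutive calendar days of non-directed movement
after at least one directed day; an unlabeled gap breaks a run. The 0.5
day-level threshold is this package's operationalization of what is
traditionally a visual GIS judgement, and is a config key. A second trigger
(`detect_return_onset`) fires when the animal re-enters a configurable
radius (default 2 km) of its release point after an excursion.

On duty-cycled data a day contributes only ~7 classified steps, so
single-day labels are binomially noisy; the supported contract is a median
onset error ≤ 1 day across replicates, not per-track exactness.

## Home-range estimation

* **Kernel and bandwidth.** Isotropic bivariate-normal kernel with a single
  smoothing parameter h. CVh maximizes the leave-one-out log-likelihood via
  bounded golden-section search over log h (default bounds 1 m to the data
  diagonal; `xatol` 1e-8 in log space). At least 5 distinct points are
  required; identical points make the objective unbounded and are rejected.
  LSCV is implemented as a secondary selector — on clustered telemetry it
  tends to undersmooth and elongate ranges, which is why CVh is the default.
* **Grid.** 50 m cells (matching the ~50 m accuracy of filtered
  fast-acquisition fixes), extent = data bounding box padded by 4h, which
  bounds truncated mass below 0.5%; total mass is asserted ≥ 0.995.
* **Isopleths.** The density threshold for a level is found by a
  descending-density cumulative sum with linear interpolation between the
  two straddling cell densities (reduces grid-resolution bias); the
  super-level set is polygonized by marching squares on a zero-padded grid
  (every contour closes), and rings are combined even-odd so nested rings
  become holes. Enclosed mass is re-integrated in tests to level ± 0.01.
* **Post-processing.** Land is removed by geometric difference before areas
  are reported (invalid geometry is repaired with a zero buffer first);
  combined species ranges are geometric unions; day/night ranges rerun the
  full pipeline (bandwidth included) independently per subset, skipping
  subsets with fewer than 5 fixes. Range-stabilization curves run the full
  95% pipeline on cumulative 5-day prefixes and flag the first day ≥ 20 days
  where successive areas change by < 10%.
* A fixed-h KDE with bandwidth h applied to draws from N(0, σ²I) has
  *expected* density N(0, (σ²+h²)I); validation against closed forms uses
  this inflated variance, and CVh-selected bandwidths carry the same mild
  positive area bias (~10–20% for n = 500), which is inherent to kernel
  home-range estimation rather than an implementation artifact.

## Habitat and protection-zone overlay

Depth bins are half-open, lower-inclusive ([0,5), [5,10), … m, positive
down) so no cell is counted twice; negative cells are treated as land and
excluded with a warning. Zone polygons are dissolved unions of cell boxes,
so band edges are resolved to the raster cell, not sub-cell. Per-range depth
fractions are fractions of total range area, with any remainder outside the
classified extent reported explicitly. Range overlap and protection-zone
residency are purely descriptive area fractions; an optional fix-relabeling
permutation test (999 permutations, seedable) is provided as an extension
and is off by default because the underlying studies state no test.

Cohort summaries use the sample SD (n−1), SE = SD/√n and the midpoint
median convention; these conventions reproduce the bundled days-tracked
table's printed statistics (dugongs mean 47.8, SE 11.7, n = 11; turtles
mean 106.5, SE 16.1, n = 10) exactly at 1-dp rounding.

## Synthetic data: what it emulates, and what it does not

`make_world` builds a coastal band with a sinusoidal-plus-noise coastline
(complexity 0 gives a straight coast), depth increasing linearly with
distance from shore (default 1 m/km), and rectangular protection zones in
the sea. `simulate_track` is a two-state correlated random walk observed on
the tag schedule (60 min dugong, 30 min turtle):

| parameter | transit | forage | rationale |
|---|---|---|---|
| mean speed (km/h) | 2.0 | 0.4 | directed travel vs. grazing drift |
| turning SD (wrapped normal) | 10° | 120° | near-straight vs. genuinely tortuous: at SD 120° only ~30% of steps pass the 45° rule, matching what "tortuous" means operationally |
| dwell (exponential mean, days) | 2 | 10 | foraging bouts dominate deployments |

Step lengths are gamma (shape 4) with mean speed × interval; land contact is
resolved by a specular bounce through the nearest coastline point. Location
classes are drawn independently of behavior (no evidence of dependence), and
positional error is Gaussian with per-class scales (10/12/30/150 m) chosen
so ~98% of draws fall within each class's nominal accuracy tier (30 m
resolved, 75 m uncertain, several hundred meters unresolved); fixes drop out
at 10% by default. `initial_dwell_days` can pin the first state's duration
for staged transit→forage scenarios with known switch times.

`sample_utilization` draws from isotropic bivariate-normal mixtures and
returns numerically integrated 50%/95% highest-density areas (600² grid over
±6 SD; the integrator is independent of the KDE code path) as recovery
truth.

The generator does **not** emulate tidal movement drivers, haul-out/basking
behavior, depth-dependent foraging preference, Argos-only (non-GPS) error
distributions, or temporally autocorrelated fix failure. Passing recovery
tests therefore demonstrates the estimators are correct for clean two-state
movement with class-tiered Gaussian error — not that they are unbiased for
every real deployment.

## Problem sizes and determinism

Validation runs use deliberately modest sizes — worlds of 20 × 15 km at
250 m bathymetry cells, tracks of 10–30 days, 500-point mixtures over
10 seeds, 20 onset replicates, 1000 random tracks for filter-oracle
equivalence — chosen so each check isolates one property while remaining
cheap to rerun. All stochastic components take explicit seeds; the pipeline
manifest is byte-identical across reruns of the same configuration.

## Known limitations

* CVh can oversmooth small-n clustered data (positive area bias, above).
* Depth-zone polygons are cell-resolution (no sub-cell interpolation), so a
  range straddling a band edge is classified at raster precision.
* The inland rule measures distance to the land polygon boundary; in
  estuaries digitized as land, legitimate up-creek fixes need the basking
  buffer or a refined coastline.
* The detachment flag is heuristic and should be reviewed, not applied
  blindly, before truncating a deployment.
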