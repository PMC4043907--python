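# seatrack

Satellite-telemetry analysis for sympatric marine megafauna — dugongs
(*Dugong dugon*) and green sea turtles (*Chelonia mydas*) foraging in the
same coastal waters. The package turns raw fast-acquisition GPS/QFP fix
tables into quality-filtered, duty-cycle-standardized tracks, foraging-phase
segmentations, fixed-kernel home ranges, and habitat/protection-zone overlay
reports that managers can compare across species and regions.

## Who it is for

Movement ecologists and marine spatial planners who need a reproducible,
scriptable version of the classic tracking workflow: filter → standardize →
segment → home range → overlay. Every stage is a library function with a thin
CLI on top, and a synthetic-data module generates coastlines, bathymetry,
protection zones and two-state animal tracks with known truth so the whole
pipeline can be validated without field data.

## The model

**QC filtering.** Fixes are gated by location class (GPS and resolved-QFP
tiers, accuracy ≤ 75 m), then cleaned by an over-speed rule against the
species' maximum sustained swimming speed (V_max = 10 km h⁻¹ for dugongs,
9.9 km h⁻¹ for green turtles), the loop-trip spike rule (a fix is dropped
when it used exactly four satellites, its inner angle is acute, and the speed
in or out exceeds V_lp = 2.0 km h⁻¹), a 30 m inland rule, and — for turtle
tags — a manufacturer quality filter (residual error > 30 or fewer than four
uplinks).

**Standardization.** Fixes are thinned to the single most accurate location
per 3-hour duty cycle (most uplinks → lowest residual/PDOP → closest to the
window's median fix time), reducing autocorrelation and tag-performance bias.

**Segmentation.** A step is *directed* when its heading deviates less than
45° from the extension of the previous step; foraging onset is the first of
at least three consecutive non-directed days following directed travel.

**Home ranges.** The utilization distribution is a fixed bivariate-normal
kernel density on a 50 m grid with the bandwidth h chosen by likelihood
cross-validation (CVh), maximizing

    Σᵢ log[ (1/(n−1)) Σ_{j≠i} K_h(xᵢ − xⱼ) ].

The 95% home range and 50% core area are the isopleth polygons enclosing
that fraction of the density mass, clipped against land before areas are
reported. LSCV is available as a secondary selector.

**Overlay.** Bathymetry is reclassified into 5 m depth zones and intersected
with each range; protection-zone residency and pairwise range overlap are
reported as area fractions; cohort statistics (mean, SE = SD/√n, median,
range) summarize days tracked and range sizes per species.

## Worked example

Recover a known utilization distribution from 500 simulated fixes:

```python
import numpy as np
from seatrack import sample_utilization, estimate_range

ms = sample_utilization([(1.0, (0.0, 0.0), 700.0)], n=500, seed=42)
ranges, bw = estimate_range(ms.points, levels=(0.95, 0.50), cell=50.0)
print(f"CVh bandwidth: {bw.h:.1f} m")
print(f"95% home range: {ranges[0.95].area_km2:.2f} km^2 "
      f"(sampling-density truth {ms.hpd_area_m2[0.95]/1e6:.2f} km^2)")
print(f"50% core area:  {ranges[0.50].area_km2:.2f} km^2 "
      f"(truth {ms.hpd_area_m2[0.5]/1e6:.2f} km^2)")
```

prints

```
CVh bandwidth: 270.9 m
95% home range: 10.88 km^2 (sampling-density truth 9.22 km^2)
50% core area:  2.52 km^2 (truth 2.13 km^2)
```

The fixes were drawn from an isotropic normal with σ = 700 m; the estimated
95% range (10.88 km²) recovers the analytic 95% highest-density area
(9.22 km² = 2πσ² ln 20) with the mild positive bias expected of a kernel
estimate smoothed by h ≈ 271 m.

Cohort statistics of the bundled per-animal days-tracked table:

```sh
$ seatrack summarize --out summary.csv
dugong: n=11 mean=47.8 SE=11.7 range=6-141
turtle: n=10 mean=106.5 SE=16.1 range=27-148
```

A full synthetic run:

```sh
seatrack simulate --seed 7 --out-world world/ --out-track track.csv
seatrack pipeline --config run.yaml --world world/
```

which writes filtered and thinned fix tables, range polygons
(`ranges.geojson`), and a `manifest.json` recording every parameter and
per-stage fix count.

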