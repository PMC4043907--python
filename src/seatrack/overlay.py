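"""Bathymetric and protection-zone overlay of home ranges, and cohort summaries.

Bathymetry rasters (depth in meters below mean sea level, positive down) are
reclassified into half-open 5 m depth zones ([0,5), [5,10), ...) and
dissolved to polygons so range polygons can be intersected with them.
Residency in named protection zones is the fraction of a range's area inside
the zone polygon.  Cohort summaries report mean, sample SD (n-1), SE, median,
min and max per group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.ops import unary_union

from .homerange import RangePolygons
from .io_telemetry import Raster

logger = logging.getLogger("seatrack")

__all__ = [
    "DepthZoneTable",
    "OverlapReport",
    "CohortSummary",
    "reclassify_depth",
    "depth_zone_table",
    "overlap_fraction",
    "zone_residency",
    "cohort_summary",
    "overlap_permutation_test",
    "load_table1_days",
]

DEPTH_BIN_M = 5.0


@dataclass
class DepthZoneTable:
    """Per-depth-zone area (km^2) and fraction of one range.

    Keys are zone lower bounds in meters; ``unclassified_km2`` is any part of
    the range outside the raster's classified extent.
    """

    animal_id: str
    level: float
    area_km2: dict[float, float] = field(default_factory=dict)
    fraction: dict[float, float] = field(default_factory=dict)
    unclassified_km2: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "animal_id": self.animal_id,
                "level": self.level,
                "zone_m": z,
                "area_km2": self.area_km2[z],
                "fraction": self.fraction[z],
            }
            for z in sorted(self.area_km2)
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class OverlapReport:
    """Pairwise range overlap: intersection area and fraction of each member."""

    id_a: str
    id_b: str
    level: float
    intersection_km2: float
    fraction_of_a: float
    fraction_of_b: float


@dataclass(frozen=True)
class CohortSummary:
    group: str
    variable: str
    n: int
    mean: float
    sd: float
    se: float
    median: float
    min: float
    max: float


def reclassify_depth(bathymetry: Raster, bin_m: float = DEPTH_BIN_M) -> dict[float, Polygon]:
    """Dissolve a depth raster into half-open depth-zone polygons.

    Returns {lower_bound_m: polygon}; bins are [0,5), [5,10), ... so no cell
    is double-counted.  Negative-depth cells are treated as land and excluded
    (with a warning).
    """
    depth = bathymetry.data
    if np.any(depth < 0):
        logger.warning("negative-depth cells treated as land and excluded")
    sea = depth >= 0
    if not sea.any():
        return {}
    zones: dict[float, Polygon] = {}
    max_bin = math.floor(depth[sea].max() / bin_m)
    for k in range(int(max_bin) + 1):
        lo = k * bin_m
        mask = sea & (depth >= lo) & (depth < lo + bin_m)
        if not mask.any():
            continue
        boxes = [
            bathymetry.cell_box(r, c) for r, c in zip(*np.nonzero(mask))
        ]
        zones[lo] = unary_union(boxes)
    return zones


def depth_zone_table(
    ranges: RangePolygons, zones: Mapping[float, Polygon]
) -> DepthZoneTable:
    """Intersect one range with the depth zones; report areas and fractions.

    Fractions are of the total range area; any remainder outside the
    classified extent is reported explicitly as unclassified.
    """
    geom = ranges.geometry
    total_km2 = geom.area / 1e6
    table = DepthZoneTable(animal_id=ranges.animal_id, level=ranges.level)
    covered = 0.0
    for lo, zpoly in sorted(zones.items()):
        a = geom.intersection(zpoly).area / 1e6
        table.area_km2[lo] = a
        table.fraction[lo] = a / total_km2 if total_km2 > 0 else 0.0
        covered += a
    table.unclassified_km2 = max(0.0, total_km2 - covered)
    return table


def overlap_fraction(a: RangePolygons, b: RangePolygons) -> OverlapReport:
    """Intersection of two same-level ranges, as area and member fractions."""
    if a.level != b.level:
        raise ValueError("overlap requires ranges at the same isopleth level")
    inter = a.geometry.intersection(b.geometry).area / 1e6
    return OverlapReport(
        id_a=a.animal_id,
        id_b=b.animal_id,
        level=a.level,
        intersection_km2=inter,
        fraction_of_a=inter / a.area_km2 if a.area_km2 > 0 else 0.0,
        fraction_of_b=inter / b.area_km2 if b.area_km2 > 0 else 0.0,
    )


def zone_residency(ranges: RangePolygons, zone: Polygon | MultiPolygon) -> float:
    """Fraction of a range's area inside a protection zone (1 - fraction is outside)."""
    if zone is None or zone.is_empty:
        return 0.0
    total = ranges.geometry.area
    if total == 0:
        return 0.0
    return float(ranges.geometry.intersection(zone).area / total)


def cohort_summary(
    values: Mapping[str, Sequence[float]], variable: str = "value"
) -> list[CohortSummary]:
    """Mean, sample SD, SE = SD/sqrt(n), median, min, max per group.

    The SD uses the n-1 denominator; the median uses the midpoint convention
    for even n.
    """
    out = []
    for group, vals in values.items():
        arr = np.asarray(list(vals), dtype=float)
        n = len(arr)
        if n == 0:
            raise ValueError(f"group {group!r} is empty")
        sd = float(arr.std(ddof=1)) if n >= 2 else 0.0
        out.append(
            CohortSummary(
                group=group,
                variable=variable,
                n=n,
                mean=float(arr.mean()),
                sd=sd,
                se=sd / math.sqrt(n),
                median=float(np.median(arr)),
                min=float(arr.min()),
                max=float(arr.max()),
            )
        )
    return out


def overlap_permutation_test(
    points_a: np.ndarray,
    points_b: np.ndarray,
    observed_overlap_km2: float,
    overlap_fn,
    n_permutations: int = 999,
    seed: int = 0,
) -> float:
    """Optional fix-relabeling permutation test for range overlap (extension).

    Pools the two animals' fixes, permutes labels, recomputes the overlap
    with ``overlap_fn(points_a, points_b) -> km^2`` and returns the
    one-sided p-value for the observed overlap being small.  Off by default
    in the pipeline; the standard outputs are descriptive fractions only.
    """
    rng = np.random.default_rng(seed)
    pool = np.vstack([points_a, points_b])
    na = len(points_a)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(pool))
        o = overlap_fn(pool[perm[:na]], pool[perm[na:]])
        if o <= observed_overlap_km2:
            count += 1
    return (count + 1) / (n_permutations + 1)


def load_table1_days() -> pd.DataFrame:
    """Per-animal days-tracked fixture (id, location, species, days_tracked)."""
    with resources.files("seatrack.data").joinpath("table1_days.csv").open() as fh:
        return pd.read_csv(fh)
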