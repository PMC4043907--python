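"""Fixed-kernel home-range estimation.

The utilization distribution is a fixed (single-bandwidth) bivariate normal
kernel density over planar coordinates, evaluated on a regular grid (50 m
default).  The smoothing bandwidth is selected by likelihood cross-validation
(CVh): h maximizing the leave-one-out log-likelihood

    sum_i log[ (1/(n-1)) sum_{j != i} K_h(x_i - x_j) ]

with K_h the isotropic bivariate normal kernel.  Least-squares
cross-validation (LSCV) is available as a secondary selector; it tends to
produce elongated, skewed ranges on clustered telemetry.  Home ranges are
the 95% isopleth polygons of the density (50% for core areas), clipped
against land before areas are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import reduce
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import MultiPolygon, Polygon
from shapely.validation import make_valid
from skimage import measure

from .io_telemetry import Track
from .standardize import tag_diurnal

__all__ = [
    "Bandwidth",
    "DensityGrid",
    "RangePolygons",
    "cvh_bandwidth",
    "lscv_bandwidth",
    "kde_grid",
    "isopleth",
    "clip_land",
    "combined_range",
    "estimate_range",
    "diurnal_ranges",
    "stabilization_curve",
]

DEFAULT_CELL_M = 50.0
DEFAULT_LEVELS = (0.95, 0.50)


@dataclass(frozen=True)
class Bandwidth:
    """Isotropic smoothing scale in meters with the selector's optimum value."""

    h: float
    objective: float
    bounds: tuple[float, float]
    selector: str = "cvh"

    def __post_init__(self) -> None:
        if not (self.bounds[0] <= self.h <= self.bounds[1]) or self.h <= 0:
            raise ValueError("bandwidth must be positive and within its search bounds")


@dataclass
class DensityGrid:
    """Regular raster of utilization-density values (per m^2).

    ``values[iy, ix]`` with iy increasing northward; cell centers at
    (xll + (ix+0.5)*cell, yll + (iy+0.5)*cell).
    """

    values: np.ndarray
    xll: float
    yll: float
    cell: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("densities must be nonnegative")
        if self.cell <= 0:
            raise ValueError("cell size must be > 0")

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell

    def total_mass(self) -> float:
        return float(self.values.sum() * self.cell_area)


@dataclass
class RangePolygons:
    """Isopleth polygon set for one animal, level and period."""

    animal_id: str
    level: float  # 0.95 home range, 0.50 core area
    geometry: Polygon | MultiPolygon
    period: str = "all"  # 'all' | 'day' | 'night' | 'month-YYYY-MM'

    @property
    def area_km2(self) -> float:
        return float(self.geometry.area) / 1e6


# --- bandwidth selection ------------------------------------------------------


def _pairwise_d2(points: np.ndarray) -> np.ndarray:
    return squareform(pdist(points, "sqeuclidean"))


def _loo_loglik(d2: np.ndarray, h: float) -> float:
    n = d2.shape[0]
    k = np.exp(-d2 / (2.0 * h * h)) / (2.0 * math.pi * h * h)
    np.fill_diagonal(k, 0.0)
    loo = k.sum(axis=1) / (n - 1)
    if np.any(loo <= 0):
        return -1e300  # finite sentinel keeps the bounded search stable
    return float(np.log(loo).sum())


def cvh_bandwidth(
    points: np.ndarray,
    bounds: tuple[float, float] | None = None,
    min_points: int = 5,
) -> Bandwidth:
    """Likelihood cross-validation bandwidth.

    Maximizes the leave-one-out log-likelihood over log h by bounded
    golden-section search.  Default bounds are [1 m, extent diagonal].
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < min_points:
        raise ValueError(f"at least {min_points} points are required")
    span = pts.max(axis=0) - pts.min(axis=0)
    diag = float(np.hypot(*span))
    if diag == 0.0:
        raise ValueError("all points identical: CVh objective is unbounded")
    if bounds is None:
        bounds = (1.0, diag)
    d2 = _pairwise_d2(pts)
    res = minimize_scalar(
        lambda lg: -_loo_loglik(d2, math.exp(lg)),
        bounds=(math.log(bounds[0]), math.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h = float(math.exp(res.x))
    return Bandwidth(h=h, objective=float(-res.fun), bounds=bounds, selector="cvh")


def lscv_bandwidth(
    points: np.ndarray,
    bounds: tuple[float, float] | None = None,
    min_points: int = 5,
) -> Bandwidth:
    """Least-squares cross-validation bandwidth (secondary selector).

    Minimizes the LSCV score of the bivariate normal kernel estimate.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n < min_points:
        raise ValueError(f"at least {min_points} points are required")
    span = pts.max(axis=0) - pts.min(axis=0)
    diag = float(np.hypot(*span))
    if diag == 0.0:
        raise ValueError("all points identical")
    if bounds is None:
        bounds = (1.0, diag)
    d2 = _pairwise_d2(pts)
    iu = np.triu_indices(n, k=1)
    d2u = d2[iu]

    def score(lg: float) -> float:
        h = math.exp(lg)
        h2 = h * h
        # integral of fhat^2: convolution kernel has variance 2h^2
        conv = np.exp(-d2u / (4.0 * h2)).sum()
        int_f2 = (n + 2.0 * conv) / (n * n * 4.0 * math.pi * h2)
        loo = np.exp(-d2u / (2.0 * h2)).sum()
        cross = 2.0 * (2.0 * loo) / (n * (n - 1) * 2.0 * math.pi * h2)
        return int_f2 - cross

    res = minimize_scalar(
        score,
        bounds=(math.log(bounds[0]), math.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h = float(math.exp(res.x))
    return Bandwidth(h=h, objective=float(res.fun), bounds=bounds, selector="lscv")


# --- density grid -------------------------------------------------------------


def kde_grid(
    points: np.ndarray,
    h: float,
    cell: float = DEFAULT_CELL_M,
    pad: float | None = None,
) -> DensityGrid:
    """Fixed-kernel density on a regular grid.

    density(cell center) = (1/n) sum_i K_h(center - x_i), extent the data
    bounding box padded by ``pad`` (default 4h, which truncates less than
    0.5% of the mass).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("no points")
    if h <= 0:
        raise ValueError("h must be > 0")
    if pad is None:
        pad = 4.0 * h
    x0, y0 = pts.min(axis=0) - pad
    x1, y1 = pts.max(axis=0) + pad
    nx = max(1, int(math.ceil((x1 - x0) / cell)))
    ny = max(1, int(math.ceil((y1 - y0) / cell)))
    cx = x0 + (np.arange(nx) + 0.5) * cell
    cy = y0 + (np.arange(ny) + 0.5) * cell
    norm = 1.0 / (2.0 * math.pi * h * h * len(pts))
    values = np.empty((ny, nx))
    # chunk over rows to bound the (rows x nx x n) temporary
    chunk = max(1, int(4e6 // (nx * len(pts)) + 1))
    for s in range(0, ny, chunk):
        e = min(ny, s + chunk)
        dx = cx[None, :, None] - pts[None, None, :, 0]
        dy = cy[s:e, None, None] - pts[None, None, :, 1]
        values[s:e] = norm * np.exp(-(dx * dx + dy * dy) / (2.0 * h * h)).sum(axis=2)
    return DensityGrid(values=values, xll=float(x0), yll=float(y0), cell=cell)


# --- isopleth extraction ------------------------------------------------------


def _mass_threshold(grid: DensityGrid, level: float) -> float:
    """Density threshold whose super-level set holds ``level`` of the mass.

    Descending-density cumulative sum with linear interpolation between the
    two straddling cell densities, which reduces grid-resolution bias.
    """
    flat = np.sort(grid.values.ravel())[::-1]
    mass = np.cumsum(flat) * grid.cell_area
    total = mass[-1]
    if total <= 0:
        raise ValueError("degenerate (all-zero) density grid")
    target = level * min(total, 1.0)
    k = int(np.searchsorted(mass, target))
    if k == 0:
        return float(flat[0])
    if k >= len(flat):
        return float(flat[-1])
    m0, m1 = mass[k - 1], mass[k]
    f = (target - m0) / (m1 - m0) if m1 > m0 else 0.0
    return float(flat[k - 1] + f * (flat[k] - flat[k - 1]))


def _rings_to_geometry(rings: list[np.ndarray]) -> Polygon | MultiPolygon:
    """Assemble closed contour rings into polygons with holes (even-odd rule)."""
    polys = []
    for ring in rings:
        if len(ring) < 4:
            continue
        p = Polygon(ring)
        if not p.is_valid:
            p = make_valid(p)
        if p.area > 0:
            polys.append(p)
    if not polys:
        return Polygon()
    geom = reduce(lambda a, b: a.symmetric_difference(b), polys)
    if geom.is_empty:
        return Polygon()
    return geom


def isopleth(
    grid: DensityGrid, level: float, animal_id: str = "", period: str = "all"
) -> RangePolygons:
    """Polygonize the density super-level set enclosing ``level`` of the mass.

    Sub-cell contouring (marching squares) at the mass threshold; the grid is
    zero-padded by one cell ring so every contour closes.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    t = _mass_threshold(grid, level)
    padded = np.pad(grid.values, 1, mode="constant", constant_values=0.0)
    rings = []
    for contour in measure.find_contours(padded, t):
        # contour columns/rows are padded-array indices; centers offset by 0.5
        xs = grid.xll + (contour[:, 1] - 1 + 0.5) * grid.cell
        ys = grid.yll + (contour[:, 0] - 1 + 0.5) * grid.cell
        rings.append(np.column_stack([xs, ys]))
    geom = _rings_to_geometry(rings)
    return RangePolygons(animal_id=animal_id, level=level, geometry=geom, period=period)


# --- polygon post-processing --------------------------------------------------


def clip_land(ranges: RangePolygons, world) -> RangePolygons:
    """Remove the land portion of a range before areas are reported."""
    land = getattr(world, "land", world)
    geom = ranges.geometry
    if not geom.is_valid:
        geom = make_valid(geom.buffer(0))
    clipped = geom.difference(land)
    return RangePolygons(ranges.animal_id, ranges.level, clipped, ranges.period)


def combined_range(ranges: Sequence[RangePolygons], animal_id: str = "combined") -> RangePolygons:
    """Union of same-level ranges across individuals (total area covered)."""
    if not ranges:
        raise ValueError("no ranges to combine")
    levels = {r.level for r in ranges}
    if len(levels) != 1:
        raise ValueError("all ranges must share the isopleth level")
    from shapely.ops import unary_union

    geom = unary_union([r.geometry for r in ranges])
    return RangePolygons(animal_id, ranges[0].level, geom, ranges[0].period)


# --- full pipeline helpers ----------------------------------------------------


def estimate_range(
    points: np.ndarray,
    levels: Iterable[float] = DEFAULT_LEVELS,
    cell: float = DEFAULT_CELL_M,
    world=None,
    animal_id: str = "",
    period: str = "all",
    selector: str = "cvh",
    bandwidth: float | None = None,
) -> tuple[dict[float, RangePolygons], Bandwidth]:
    """CVh (or LSCV / fixed h) -> KDE -> isopleths -> optional land clipping."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if bandwidth is not None:
        bw = Bandwidth(h=bandwidth, objective=math.nan, bounds=(bandwidth, bandwidth), selector="fixed")
    elif selector == "lscv":
        bw = lscv_bandwidth(pts)
    else:
        bw = cvh_bandwidth(pts)
    grid = kde_grid(pts, bw.h, cell=cell)
    out: dict[float, RangePolygons] = {}
    for lv in levels:
        rp = isopleth(grid, lv, animal_id=animal_id, period=period)
        if world is not None:
            rp = clip_land(rp, world)
        out[lv] = rp
    return out, bw


def diurnal_ranges(
    track: Track,
    levels: Iterable[float] = DEFAULT_LEVELS,
    cell: float = DEFAULT_CELL_M,
    world=None,
    min_points: int = 5,
    selector: str = "cvh",
) -> dict[str, Optional[dict[float, RangePolygons]]]:
    """Independent day (06:00-18:00 local) and night range estimates.

    The full pipeline runs separately on each subset; a subset with fewer
    than ``min_points`` fixes yields None.
    """
    import logging

    out: dict[str, Optional[dict[float, RangePolygons]]] = {}
    for period in ("day", "night"):
        sub = [f for f in track.fixes if tag_diurnal(f) == period]
        if len(sub) < min_points:
            logging.getLogger("seatrack").warning(
                "%s: only %d %s fixes; no %s range", track.animal_id, len(sub), period, period
            )
            out[period] = None
            continue
        pts = np.array([(f.x, f.y) for f in sub])
        ranges, _ = estimate_range(
            pts, levels=levels, cell=cell, world=world,
            animal_id=track.animal_id, period=period, selector=selector,
        )
        out[period] = ranges
    return out


def stabilization_curve(
    track: Track,
    step_days: float = 5.0,
    min_days: float = 20.0,
    cell: float = DEFAULT_CELL_M,
    level: float = 0.95,
    world=None,
    rel_tol: float = 0.10,
) -> tuple[list[tuple[float, float]], Optional[float]]:
    """Cumulative-prefix 95% range areas versus days tracked.

    Runs the full pipeline on each ``step_days`` prefix of the track and
    returns [(days, area_km2), ...] plus the first day at or beyond
    ``min_days`` where the successive relative area change drops below
    ``rel_tol`` (None if the curve never plateaus).
    """
    fixes = track.fixes
    if not fixes:
        raise ValueError("empty track")
    t0 = fixes[0].timestamp
    span_days = (fixes[-1].timestamp - t0).total_seconds() / 86400.0
    series: list[tuple[float, float]] = []
    d = step_days
    while d <= span_days + 1e-9:
        sub = [f for f in fixes if (f.timestamp - t0).total_seconds() / 86400.0 <= d]
        if len(sub) >= 5 and len({(f.x, f.y) for f in sub}) > 1:
            pts = np.array([(f.x, f.y) for f in sub])
            ranges, _ = estimate_range(pts, levels=(level,), cell=cell, world=world,
                                       animal_id=track.animal_id)
            series.append((d, ranges[level].area_km2))
        d += step_days
    plateau = None
    for (d0, a0), (d1, a1) in zip(series, series[1:]):
        if d1 >= min_days and a0 > 0 and abs(a1 - a0) / a0 < rel_tol:
            plateau = d1
            break
    return series, plateau
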