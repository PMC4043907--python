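"""Quality-control filters for GPS/QFP telemetry.

Implements the standard megafauna-tracking cleanup chain: location-class
gating (retain GPS and resolved-QFP tiers, accuracy <= 75 m), over-speed
removal against a species maximum sustained swimming speed (10 km/h dugong,
9.9 km/h green turtle), the loop-trip inner-angle spike filter (Vlp
2.0 km/h), removal of fixes more than 30 m inland, the turtle tag quality
filter (residual error > 30 or fewer than four satellite uplinks), and
tag-detachment signature flagging.

Every filter returns ``(filtered_track, FilterReport)`` with the removed
indices; filters are idempotent and preserve fix order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import Point
from shapely.prepared import prep

from .io_telemetry import Fix, LocClass, Track

logger = logging.getLogger("seatrack")

__all__ = [
    "FilterConfig",
    "FilterReport",
    "filter_by_class",
    "speed_between",
    "filter_overspeed",
    "inner_angle",
    "filter_loop_trip",
    "filter_inland",
    "filter_turtle_quality",
    "flag_detachment",
    "filter_species_chain",
]

#: classes retained for fine-scale analysis (accuracy <= 75 m)
DEFAULT_ALLOWED_CLASSES = frozenset(
    {LocClass.GPS_SUCCEEDED, LocClass.QFP_RESOLVED, LocClass.QFP_UNCERTAIN}
)


@dataclass
class FilterConfig:
    """Thresholds for the QC chain; defaults are the field-standard values."""

    allowed_classes: frozenset = DEFAULT_ALLOWED_CLASSES
    vmax_kmh: float = 10.0  # dugong; use 9.9 for green turtles
    vlp_kmh: float = 2.0  # loop-trip speed (turtle spike filter)
    max_residual: float = 30.0
    min_satellites: int = 4
    max_inland_m: float = 30.0
    angle_acute_deg: float = 90.0
    basking_buffer_m: float = 0.0  # extra inland allowance for basking turtles
    compare_to_raw_predecessor: bool = False  # alternative over-speed anchoring

    def __post_init__(self) -> None:
        for name in ("vmax_kmh", "vlp_kmh", "max_residual", "max_inland_m", "angle_acute_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class FilterReport:
    """Per-rule accounting of removed fixes; removed + retained = input."""

    rule: str
    n_input: int
    removed_indices: list[int] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_indices)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


def filter_by_class(track: Track, cfg: FilterConfig) -> tuple[Track, FilterReport]:
    """Retain only fixes whose location class is in the allowed set."""
    removed = [i for i, f in enumerate(track.fixes) if f.loc_class not in cfg.allowed_classes]
    kept = [f for i, f in enumerate(track.fixes) if i not in set(removed)]
    return track.with_fixes(kept), FilterReport("class", len(track.fixes), removed)


def speed_between(a: Fix, b: Fix) -> float:
    """Straight-line speed between two fixes in km/h (planar distance / time)."""
    dt_h = (b.timestamp - a.timestamp).total_seconds() / 3600.0
    if dt_h <= 0:
        raise ValueError("fixes must be strictly ordered in time")
    dist_km = math.hypot(b.x - a.x, b.y - a.y) / 1000.0
    return dist_km / dt_h


def filter_overspeed(track: Track, cfg: FilterConfig) -> tuple[Track, FilterReport]:
    """Remove fixes implying speeds above the species maximum.

    Forward pass against the last retained fix (keeping the earlier fix of an
    offending pair), repeated to a fixed point.  With
    ``compare_to_raw_predecessor`` the speed check instead uses each fix's
    immediate raw predecessor.
    """
    fixes = track.fixes
    removed: set[int] = set()
    if cfg.compare_to_raw_predecessor:
        changed = True
        while changed:
            changed = False
            for i in range(1, len(fixes)):
                if i in removed or (i - 1) in removed:
                    continue
                if speed_between(fixes[i - 1], fixes[i]) > cfg.vmax_kmh:
                    removed.add(i)
                    changed = True
    else:
        last: Optional[int] = None
        for i in range(len(fixes)):
            if last is None:
                last = i
                continue
            if speed_between(fixes[last], fixes[i]) > cfg.vmax_kmh:
                removed.add(i)
            else:
                last = i
    kept = [f for i, f in enumerate(fixes) if i not in removed]
    return track.with_fixes(kept), FilterReport("overspeed", len(fixes), sorted(removed))


def inner_angle(p_prev: tuple[float, float], p: tuple[float, float], p_next: tuple[float, float]) -> float:
    """Angle (degrees, in [0, 180]) at vertex p between segments to its neighbours.

    180 deg means collinear forward motion; 0 deg an exact backtrack.  Acute
    values flag out-and-back spike artifacts.
    """
    u = (p_prev[0] - p[0], p_prev[1] - p[1])
    v = (p_next[0] - p[0], p_next[1] - p[1])
    nu, nv = math.hypot(*u), math.hypot(*v)
    if nu == 0 or nv == 0:
        raise ValueError("coincident points have no inner angle")
    c = (u[0] * v[0] + u[1] * v[1]) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _loop_trip_pass(fixes: list[Fix], cfg: FilterConfig) -> Optional[int]:
    """Index of the first fix violating the Vmax or loop-trip rule, else None."""
    for i in range(1, len(fixes)):
        if speed_between(fixes[i - 1], fixes[i]) > cfg.vmax_kmh:
            return i
    for i in range(len(fixes)):
        f = fixes[i]
        if f.n_satellites != 4:
            continue
        if i == 0 or i == len(fixes) - 1:
            continue
        a, b = fixes[i - 1], fixes[i + 1]
        try:
            ang = inner_angle((a.x, a.y), (f.x, f.y), (b.x, b.y))
        except ValueError:
            continue
        if ang >= cfg.angle_acute_deg:
            continue
        v_in = speed_between(a, f)
        v_out = speed_between(f, b)
        if v_in > cfg.vlp_kmh or v_out > cfg.vlp_kmh:
            return i
    return None


def filter_loop_trip(track: Track, cfg: FilterConfig) -> tuple[Track, FilterReport]:
    """Data-driven spike filter for turtle tracks.

    Removes fixes whose speed from the previous retained fix exceeds Vmax, or
    for which all of: the fix used exactly four source satellites, its inner
    angle is acute, and the speed either into or out of it exceeds the
    loop-trip speed Vlp.  Re-evaluated to a fixed point.
    """
    fixes = list(track.fixes)
    index_of = {id(f): i for i, f in enumerate(track.fixes)}
    removed: list[int] = []
    while True:
        bad = _loop_trip_pass(fixes, cfg)
        if bad is None:
            break
        removed.append(index_of[id(fixes[bad])])
        del fixes[bad]
    return track.with_fixes(fixes), FilterReport("loop_trip", len(track.fixes), sorted(removed))


def filter_inland(track: Track, world, cfg: FilterConfig) -> tuple[Track, FilterReport]:
    """Remove fixes more than ``max_inland_m`` inland of the coastline.

    Fixes at sea, on the coastline, or within the inland allowance (the error
    of the most precise QFP tier, 30 m, plus any basking buffer) are retained.
    """
    land = getattr(world, "land", world)
    if land is None:
        raise ValueError("a land polygon is required for the inland filter")
    land_prep = prep(land)
    allow = cfg.max_inland_m + cfg.basking_buffer_m
    removed = []
    for i, f in enumerate(track.fixes):
        pt = Point(f.x, f.y)
        if land_prep.contains(pt) and land.boundary.distance(pt) > allow:
            removed.append(i)
    kept = [f for i, f in enumerate(track.fixes) if i not in set(removed)]
    return track.with_fixes(kept), FilterReport("inland", len(track.fixes), removed)


def filter_turtle_quality(track: Track, cfg: FilterConfig) -> tuple[Track, FilterReport]:
    """Manufacturer quality filter for turtle tags.

    Excludes fixes with residual error greater than 30 (boundary inclusive:
    exactly 30 is retained) or fewer than four satellite uplinks; a missing
    residual fails the filter and is logged.
    """
    removed = []
    for i, f in enumerate(track.fixes):
        if f.residual_error is None:
            logger.warning("fix %d of %s has no residual error; removed", i, track.animal_id)
            removed.append(i)
        elif f.residual_error > cfg.max_residual or f.n_satellites < cfg.min_satellites:
            removed.append(i)
    kept = [f for i, f in enumerate(track.fixes) if i not in set(removed)]
    return track.with_fixes(kept), FilterReport("turtle_quality", len(track.fixes), removed)


def flag_detachment(
    track: Track,
    straight_steps: int = 12,
    stationary_radius_m: float = 100.0,
    stationary_days: float = 3.0,
    heading_tol_deg: float = 10.0,
    speed_tol_frac: float = 0.2,
) -> Optional[int]:
    """Index of the first fix where a tag-detachment signature begins, or None.

    Signatures: (1) a run of >= ``straight_steps`` consecutive GPS-succeeded
    fixes at exactly the nominal schedule; (2) prolonged straight-line drift
    (>= ``straight_steps`` steps with heading deviation < 10 deg and speed
    variation < 20%); (3) all fixes within ``stationary_radius_m`` of one
    point for >= ``stationary_days``.  Flag only — truncation is a user call.
    """
    fixes = track.fixes
    n = len(fixes)
    if n == 0:
        raise ValueError("track must be non-empty")
    candidates: list[int] = []

    # (1) metronomic GPS-succeeded runs
    run_start, run = 0, 0
    sched = track.schedule_minutes * 60.0
    for i in range(1, n):
        dt = (fixes[i].timestamp - fixes[i - 1].timestamp).total_seconds()
        ok = (
            fixes[i].loc_class == LocClass.GPS_SUCCEEDED
            and fixes[i - 1].loc_class == LocClass.GPS_SUCCEEDED
            and abs(dt - sched) < 1.0
        )
        if ok:
            if run == 0:
                run_start = i - 1
            run += 1
            if run >= straight_steps:
                candidates.append(run_start)
                break
        else:
            run = 0

    # (2) straight, constant-speed drift
    if n >= 3:
        headings = []
        speeds = []
        for i in range(1, n):
            dx, dy = fixes[i].x - fixes[i - 1].x, fixes[i].y - fixes[i - 1].y
            headings.append(math.degrees(math.atan2(dy, dx)))
            speeds.append(speed_between(fixes[i - 1], fixes[i]))
        run_start, run = 0, 0
        for i in range(1, len(headings)):
            dev = abs((headings[i] - headings[i - 1] + 180.0) % 360.0 - 180.0)
            mean_sp = 0.5 * (speeds[i] + speeds[i - 1])
            sp_var = abs(speeds[i] - speeds[i - 1]) / mean_sp if mean_sp > 0 else 1.0
            if dev < heading_tol_deg and sp_var < speed_tol_frac:
                if run == 0:
                    run_start = i - 1
                run += 1
                if run >= straight_steps:
                    candidates.append(run_start)
                    break
            else:
                run = 0

    # (3) stationary signal
    for i in range(n):
        j = i
        while j + 1 < n and math.hypot(
            fixes[j + 1].x - fixes[i].x, fixes[j + 1].y - fixes[i].y
        ) <= stationary_radius_m:
            j += 1
        span_days = (fixes[j].timestamp - fixes[i].timestamp).total_seconds() / 86400.0
        if span_days >= stationary_days:
            candidates.append(i)
            break

    return min(candidates) if candidates else None


def filter_species_chain(
    track: Track, world, cfg: FilterConfig
) -> tuple[Track, list[FilterReport]]:
    """Apply the species-appropriate QC chain in order.

    Dugongs: class gating, over-speed, inland.  Turtles: tag quality first,
    then the Vmax/loop-trip filter, then the inland rule (with any basking
    buffer).
    """
    reports: list[FilterReport] = []
    if track.species == "dugong":
        track, r = filter_by_class(track, cfg)
        reports.append(r)
        track, r = filter_overspeed(track, cfg)
        reports.append(r)
        track, r = filter_inland(track, world, cfg)
        reports.append(r)
    else:
        track, r = filter_turtle_quality(track, cfg)
        reports.append(r)
        track, r = filter_loop_trip(track, cfg)
        reports.append(r)
        track, r = filter_inland(track, world, cfg)
        reports.append(r)
    return track, reports
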