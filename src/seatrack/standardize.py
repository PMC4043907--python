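"""Duty-cycle standardization and temporal tagging.

After QC filtering, fixes are thinned to one best location per 3-hour
duty-cycle window to reduce autocorrelation and equalize tag performance
across animals.  Windows are anchored at local midnight ([00:00,03:00),
[03:00,06:00), ...), matching the 06:00/18:00 diurnal boundaries.  The best
fix in a window is chosen lexicographically: most satellite uplinks, then
lowest residual error (turtle tags) or lowest positional dilution of
precision (dugong tags), then closest to the median member time, then
earliest.  Thinning is a pure subset operation — coordinates are never
altered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

from .io_telemetry import Fix, Track

__all__ = [
    "DutyWindow",
    "assign_windows",
    "select_best_fix",
    "duty_cycle_thin",
    "tag_diurnal",
    "split_by_month",
]

DAY_START_HOUR = 6  # local day runs 06:00-18:00
DAY_END_HOUR = 18


@dataclass
class DutyWindow:
    """One duty-cycle window: start (local), fixed length, member fixes."""

    start: datetime
    length_h: float
    fixes: list[Fix] = field(default_factory=list)
    chosen: Fix | None = None


def assign_windows(track: Track, window_h: float = 3.0) -> list[DutyWindow]:
    """Bin fixes into half-open windows anchored at local midnight.

    Each fix falls in exactly one window; empty windows are omitted.
    """
    if window_h <= 0:
        raise ValueError("window_h must be > 0")
    windows: dict[datetime, DutyWindow] = {}
    for f in track.fixes:
        t = f.timestamp
        midnight = t.replace(hour=0, minute=0, second=0, microsecond=0)
        hours = (t - midnight).total_seconds() / 3600.0
        k = int(hours // window_h)
        start = midnight + timedelta(hours=k * window_h)
        w = windows.setdefault(start, DutyWindow(start=start, length_h=window_h))
        w.fixes.append(f)
    return [windows[k] for k in sorted(windows)]


def _median_time(fixes: list[Fix]) -> datetime:
    """Median of member timestamps (midpoint of the two middle values for even n)."""
    ts = sorted(f.timestamp for f in fixes)
    n = len(ts)
    if n % 2 == 1:
        return ts[n // 2]
    a, b = ts[n // 2 - 1], ts[n // 2]
    return a + (b - a) / 2


def select_best_fix(window: DutyWindow, quality_field: str = "pdop") -> Fix:
    """Most accurate fix in a duty-cycle window.

    Hierarchy: (1) greatest number of satellite uplinks; (2) lowest
    ``quality_field`` value ('residual_error' for turtle tags, 'pdop' for
    dugong tags; missing values rank last); (3) closest to the median member
    time; remaining exact ties go to the earliest fix.
    """
    if not window.fixes:
        raise ValueError("window has no member fixes")
    med = _median_time(window.fixes)

    def key(f: Fix):
        q = getattr(f, quality_field)
        q = math.inf if q is None else q
        return (-f.n_satellites, q, abs((f.timestamp - med).total_seconds()), f.timestamp)

    best = min(window.fixes, key=key)
    window.chosen = best
    return best


def duty_cycle_thin(track: Track, window_h: float = 3.0) -> Track:
    """One best fix per duty-cycle window; at most ceil(span/window) fixes remain."""
    quality = "residual_error" if track.species == "turtle" else "pdop"
    chosen = [select_best_fix(w, quality) for w in assign_windows(track, window_h)]
    chosen.sort(key=lambda f: f.timestamp)
    return track.with_fixes(chosen)


def tag_diurnal(fix: Fix) -> str:
    """'day' iff the local time is in [06:00, 18:00), else 'night'."""
    h = fix.timestamp.hour + fix.timestamp.minute / 60.0 + fix.timestamp.second / 3600.0
    return "day" if DAY_START_HOUR <= h < DAY_END_HOUR else "night"


def split_by_month(track: Track) -> dict[tuple[int, int], Track]:
    """Partition fixes by local calendar month; keys are (year, month)."""
    groups: dict[tuple[int, int], list[Fix]] = {}
    for f in track.fixes:
        groups.setdefault((f.timestamp.year, f.timestamp.month), []).append(f)
    return {k: track.with_fixes(v) for k, v in sorted(groups.items())}
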