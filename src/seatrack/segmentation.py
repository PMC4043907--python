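"""Transit/foraging segmentation of a track.

Migrating turtles show directed, straight-line movement; foraging shows
tortuous short-distance movement.  A step is classified *directed* when the
trajectory to the next location deviates less than 45 degrees to either side
from the extension of the previous two locations.  A local day is
*non-directed* when fewer than half its steps are directed, and foraging
onset is the first day of a run of at least three consecutive non-directed
days following at least one directed day; all fixes from the onset day
onward constitute the foraging data set.  An alternative trigger fires when
the animal returns within a configurable radius of its release point after a
directed phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional

from .io_telemetry import Track

__all__ = [
    "StepClass",
    "Phase",
    "classify_steps",
    "classify_days",
    "detect_foraging_onset",
    "detect_return_onset",
    "segment_phases",
]


@dataclass(frozen=True)
class StepClass:
    """Heading deviation (degrees in [0, 180]) and label for one step."""

    index: int  # index of the focal fix i (step i -> i+1 judged against i-1 -> i)
    deviation_deg: float
    label: str  # 'directed' | 'tortuous'


@dataclass(frozen=True)
class Phase:
    label: str  # 'transit' | 'foraging'
    start: date
    end: date


def classify_steps(track: Track, angle_deg: float = 45.0) -> list[StepClass]:
    """Classify each step as directed or tortuous by heading deviation.

    For each interior fix i, the deviation is the angle between the bearing
    of the incoming step (i-1 -> i), extended, and the outgoing step
    (i -> i+1).  Directed iff deviation < ``angle_deg`` (strict).
    """
    fixes = track.fixes
    if len(fixes) < 3:
        raise ValueError("at least 3 fixes are required to classify steps")
    out: list[StepClass] = []
    for i in range(1, len(fixes) - 1):
        a, b, c = fixes[i - 1], fixes[i], fixes[i + 1]
        h_in = math.atan2(b.y - a.y, b.x - a.x)
        h_out = math.atan2(c.y - b.y, c.x - b.x)
        dev = abs((math.degrees(h_out - h_in) + 180.0) % 360.0 - 180.0)
        out.append(StepClass(i, dev, "directed" if dev < angle_deg else "tortuous"))
    return out


def classify_days(
    track: Track, steps: list[StepClass], directed_fraction: float = 0.5
) -> dict[date, str]:
    """Label each local calendar day 'directed' or 'non-directed'.

    A day is non-directed iff the fraction of directed steps that day is
    below ``directed_fraction`` (a day exactly at the threshold counts as
    directed).  Days with no steps are skipped.
    """
    per_day: dict[date, list[StepClass]] = {}
    for s in steps:
        d = track.fixes[s.index].timestamp.date()
        per_day.setdefault(d, []).append(s)
    labels: dict[date, str] = {}
    for d in sorted(per_day):
        group = per_day[d]
        frac = sum(1 for s in group if s.label == "directed") / len(group)
        labels[d] = "directed" if frac >= directed_fraction else "non-directed"
    return labels


def detect_foraging_onset(day_labels: dict[date, str], min_days: int = 3) -> Optional[date]:
    """First date starting a run of >= min_days consecutive non-directed days
    after at least one earlier directed day; None if no such run exists.

    The run must cover consecutive calendar dates (an unlabeled gap breaks it).
    """
    if not day_labels:
        raise ValueError("at least one labeled day is required")
    days = sorted(day_labels)
    seen_directed = False
    for i, d in enumerate(days):
        if day_labels[d] == "directed":
            seen_directed = True
            continue
        if not seen_directed:
            continue
        run = 1
        j = i
        while (
            j + 1 < len(days)
            and days[j + 1] == days[j] + timedelta(days=1)
            and day_labels[days[j + 1]] == "non-directed"
            and run < min_days
        ):
            run += 1
            j += 1
        if run >= min_days:
            return d
    return None


def detect_return_onset(
    track: Track, release_xy: tuple[float, float], radius_m: float = 2000.0
) -> Optional[date]:
    """Date the animal first returns within ``radius_m`` of the release point
    after having been outside it (post-release homing trigger); None if never.
    """
    away = False
    for f in track.fixes:
        d = math.hypot(f.x - release_xy[0], f.y - release_xy[1])
        if d > radius_m:
            away = True
        elif away:
            return f.timestamp.date()
    return None


def segment_phases(
    track: Track,
    angle_deg: float = 45.0,
    directed_fraction: float = 0.5,
    min_days: int = 3,
) -> tuple[list[Phase], Optional[date]]:
    """Full segmentation: step classes -> day labels -> phases and onset date."""
    steps = classify_steps(track, angle_deg)
    labels = classify_days(track, steps, directed_fraction)
    onset = detect_foraging_onset(labels, min_days)
    days = sorted(labels)
    phases: list[Phase] = []
    if onset is None:
        phases.append(Phase("transit", days[0], days[-1]))
    else:
        if onset > days[0]:
            phases.append(Phase("transit", days[0], onset - timedelta(days=1)))
        phases.append(Phase("foraging", onset, days[-1]))
    return phases, onset
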