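"""Reading and writing telemetry fix tables, polygon sets and rasters.

Coordinates are planar (UTM-style) meters throughout; the package performs
no geodetic math.  Timestamps carry an explicit fixed local (UTC) offset and
all day/night and duty-cycle logic downstream uses that local clock.

Fix tables are comma-delimited CSV with a header (UTF-8); the column names
are configurable through :class:`ColumnMap`.  Polygons are GeoJSON, rasters
are ESRI ASCII grids — both plain-text formats.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

logger = logging.getLogger("seatrack")

__all__ = [
    "LocClass",
    "Fix",
    "Track",
    "ColumnMap",
    "Raster",
    "FormatError",
    "read_fixes",
    "write_fixes",
    "write_polygons",
    "read_polygons",
    "read_ascii_grid",
    "write_ascii_grid",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected table layout."""


class LocClass(str, Enum):
    """Location-quality class of a fix.

    GPS fixes are the most accurate; Quick Fix Pseudoranging (QFP) fallback
    positions come in three accuracy tiers (resolved ≤30 m, resolved-uncertain
    ≤75 m, unresolved within several hundred meters).
    """

    GPS_SUCCEEDED = "GPS_SUCCEEDED"
    QFP_RESOLVED = "QFP_RESOLVED"
    QFP_UNCERTAIN = "QFP_UNCERTAIN"
    QFP_UNRESOLVED = "QFP_UNRESOLVED"
    OTHER = "OTHER"


@dataclass(frozen=True)
class Fix:
    """One telemetry location with quality metadata.

    ``x``/``y`` are planar meters (easting/northing).  ``residual_error`` and
    ``pdop`` are unitless nonnegative quality metrics and may be absent.
    """

    animal_id: str
    timestamp: datetime  # tz-aware with fixed local offset
    x: float
    y: float
    loc_class: LocClass = LocClass.OTHER
    n_satellites: int = 0
    residual_error: Optional[float] = None
    pdop: Optional[float] = None

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None:
            raise ValueError("Fix timestamps must carry an explicit UTC offset")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("fix coordinates must be finite")
        if self.n_satellites < 0:
            raise ValueError("n_satellites must be >= 0")


@dataclass
class Track:
    """Time-ordered fixes for one animal.

    ``schedule_minutes`` is the nominal fix interval of the tag programme
    (60 for dugong tags, 30 for turtle tags).
    """

    animal_id: str
    species: str = "dugong"  # 'dugong' | 'turtle'
    fixes: list[Fix] = field(default_factory=list)
    schedule_minutes: int = 60

    def __post_init__(self) -> None:
        if self.species not in ("dugong", "turtle"):
            raise ValueError(f"unknown species {self.species!r}")
        for f in self.fixes:
            if f.animal_id != self.animal_id:
                raise ValueError("all fixes must share the track's animal_id")
        times = [f.timestamp for f in self.fixes]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("fixes must be strictly increasing in time")

    def __len__(self) -> int:
        return len(self.fixes)

    def xy(self) -> np.ndarray:
        """(n, 2) array of planar coordinates in meters."""
        return np.array([(f.x, f.y) for f in self.fixes], dtype=float).reshape(-1, 2)

    def with_fixes(self, fixes: Sequence[Fix]) -> "Track":
        return Track(self.animal_id, self.species, list(fixes), self.schedule_minutes)


@dataclass
class ColumnMap:
    """Names of the CSV columns holding each fix field.

    Only ``timestamp``, ``x`` and ``y`` are mandatory in the file; quality
    columns that are absent are stored as missing on the Fix.
    """

    animal_id: str = "animal_id"
    timestamp: str = "timestamp"
    x: str = "x"
    y: str = "y"
    loc_class: str = "loc_class"
    n_satellites: str = "n_satellites"
    residual_error: str = "residual_error"
    pdop: str = "pdop"
    species: str = "species"
    schedule_minutes: str = "schedule_minutes"


def _parse_loc_class(value) -> LocClass:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return LocClass.OTHER
    try:
        return LocClass(str(value).strip().upper())
    except ValueError:
        return LocClass.OTHER


def _opt_float(value) -> Optional[float]:
    if value is None or value == "":
        return None
    v = float(value)
    return None if math.isnan(v) else v


def read_fixes(
    path: str | Path,
    dialect: ColumnMap | None = None,
    xy_transform: Callable[[float, float], tuple[float, float]] | None = None,
) -> list[Track]:
    """Read a fix-table CSV into one Track per animal, time-sorted.

    Duplicate (animal, timestamp) rows collapse to the first occurrence with
    a logged warning.  ``xy_transform``, if given, maps the file's raw
    coordinate pair (e.g. lon/lat) to planar meters; the package itself does
    no geodetic math.
    """
    cm = dialect or ColumnMap()
    df = pd.read_csv(path)
    if df.empty and len(df.columns) == 0:
        raise FormatError(f"{path}: no header row")
    for col in (cm.timestamp, cm.x, cm.y):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    tracks: list[Track] = []
    has_animal = cm.animal_id in df.columns
    animal_col = df[cm.animal_id].astype(str) if has_animal else pd.Series(["animal"] * len(df))
    for animal_id, sub in df.groupby(animal_col, sort=True):
        fixes = []
        for idx, row in sub.iterrows():
            raw_ts = row[cm.timestamp]
            try:
                ts = pd.Timestamp(raw_ts)
            except (ValueError, TypeError) as exc:
                # line number = header + 1-based data row
                raise FormatError(
                    f"{path}: line {idx + 2}: unparseable timestamp {raw_ts!r}"
                ) from exc
            if ts is pd.NaT or ts.tzinfo is None:
                raise FormatError(
                    f"{path}: line {idx + 2}: missing or offset-less timestamp {raw_ts!r}"
                )
            x, y = float(row[cm.x]), float(row[cm.y])
            if xy_transform is not None:
                x, y = xy_transform(x, y)
            fixes.append(
                Fix(
                    animal_id=str(animal_id),
                    timestamp=ts.to_pydatetime(),
                    x=x,
                    y=y,
                    loc_class=_parse_loc_class(row.get(cm.loc_class)),
                    n_satellites=int(row[cm.n_satellites])
                    if cm.n_satellites in sub.columns and not pd.isna(row[cm.n_satellites])
                    else 0,
                    residual_error=_opt_float(row.get(cm.residual_error)),
                    pdop=_opt_float(row.get(cm.pdop)),
                )
            )
        fixes.sort(key=lambda f: f.timestamp)
        deduped: list[Fix] = []
        for f in fixes:
            if deduped and f.timestamp == deduped[-1].timestamp:
                logger.warning(
                    "dropping duplicate fix for %s at %s", animal_id, f.timestamp.isoformat()
                )
                continue
            deduped.append(f)
        species = "dugong"
        if cm.species in sub.columns and not sub[cm.species].isna().all():
            species = str(sub[cm.species].iloc[0])
        schedule = 60
        if cm.schedule_minutes in sub.columns and not sub[cm.schedule_minutes].isna().all():
            schedule = int(sub[cm.schedule_minutes].iloc[0])
        tracks.append(Track(str(animal_id), species, deduped, schedule))
    return tracks


def write_fixes(tracks: Iterable[Track], path: str | Path, dialect: ColumnMap | None = None) -> None:
    """Write tracks back to the CSV dialect :func:`read_fixes` reads."""
    cm = dialect or ColumnMap()
    rows = []
    for tr in tracks:
        for f in tr.fixes:
            rows.append(
                {
                    cm.animal_id: f.animal_id,
                    cm.species: tr.species,
                    cm.schedule_minutes: tr.schedule_minutes,
                    cm.timestamp: f.timestamp.isoformat(),
                    cm.x: repr(f.x),
                    cm.y: repr(f.y),
                    cm.loc_class: f.loc_class.value,
                    cm.n_satellites: f.n_satellites,
                    cm.residual_error: "" if f.residual_error is None else f.residual_error,
                    cm.pdop: "" if f.pdop is None else f.pdop,
                }
            )
    cols = [
        cm.animal_id,
        cm.species,
        cm.schedule_minutes,
        cm.timestamp,
        cm.x,
        cm.y,
        cm.loc_class,
        cm.n_satellites,
        cm.residual_error,
        cm.pdop,
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# --- polygons (GeoJSON) ----------------------------------------------------


def write_polygons(ranges, path: str | Path) -> None:
    """Write RangePolygons (one object or a list) as a GeoJSON FeatureCollection.

    Each feature carries animal_id, isopleth level and area_km2 properties.
    An empty polygon set yields an empty feature collection.
    """
    from .homerange import RangePolygons  # local import avoids a cycle

    if isinstance(ranges, RangePolygons):
        ranges = [ranges]
    features = []
    for rp in ranges:
        geom = rp.geometry
        if geom is None or geom.is_empty:
            continue
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "animal_id": rp.animal_id,
                    "level": rp.level,
                    "area_km2": rp.area_km2,
                    "period": rp.period,
                },
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc), encoding="utf-8")


def read_polygons(path: str | Path):
    """Read a GeoJSON FeatureCollection back into a list of RangePolygons."""
    from .homerange import RangePolygons

    fc = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for feat in fc.get("features", []):
        props = feat.get("properties", {})
        out.append(
            RangePolygons(
                animal_id=props.get("animal_id", ""),
                level=float(props.get("level", 0.95)),
                geometry=shape(feat["geometry"]),
                period=props.get("period", "all"),
            )
        )
    return out


# --- rasters (ESRI ASCII grid) ---------------------------------------------


@dataclass
class Raster:
    """Regular grid of values with planar cell geometry.

    ``data[0, 0]`` is the north-west (top-left) cell, matching the ESRI
    ASCII row order.  ``xll``/``yll`` locate the lower-left corner of the
    grid; ``cellsize`` is in meters.
    """

    data: np.ndarray
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be > 0")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of cell-center coordinates, shaped like data."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def cell_box(self, row: int, col: int):
        from shapely.geometry import box

        x0 = self.xll + col * self.cellsize
        y1 = self.yll + (self.nrows - row) * self.cellsize
        return box(x0, y1 - self.cellsize, x0 + self.cellsize, y1)


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.xll!r}\n"
        f"yllcorner {raster.yll!r}\n"
        f"cellsize {raster.cellsize!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in raster.data)
    Path(path).write_text(header + body + "\n", encoding="utf-8")


def read_ascii_grid(path: str | Path) -> Raster:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols",
        "nrows",
        "xllcorner",
        "yllcorner",
        "cellsize",
        "nodata_value",
    ):
        key, val = lines[i].split()
        hdr[key.lower()] = float(val)
        i += 1
    data = np.array([[float(v) for v in ln.split()] for ln in lines[i:] if ln.strip()])
    if data.shape != (int(hdr["nrows"]), int(hdr["ncols"])):
        raise FormatError(f"{path}: grid body does not match declared nrows/ncols")
    return Raster(
        data=data,
        xll=hdr["xllcorner"],
        yll=hdr["yllcorner"],
        cellsize=hdr["cellsize"],
        nodata=hdr.get("nodata_value", -9999.0),
    )
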