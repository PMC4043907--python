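"""Minimal static map helper: world, fixes and range polygons on one axis."""

from __future__ import annotations

from typing import Iterable, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from shapely.geometry import MultiPolygon, Polygon

from .homerange import RangePolygons
from .io_telemetry import Track
from .synthetic import World

__all__ = ["plot_map"]


def _draw_geom(ax, geom, **kwargs):
    polys = geom.geoms if isinstance(geom, MultiPolygon) else [geom]
    for p in polys:
        if p.is_empty or not isinstance(p, Polygon):
            continue
        ax.fill(*p.exterior.xy, **kwargs)
        for ring in p.interiors:
            ax.fill(*ring.xy, color="white")


def plot_map(
    world: Optional[World] = None,
    tracks: Iterable[Track] = (),
    ranges: Iterable[RangePolygons] = (),
    path: Optional[str] = None,
):
    """Static planar map of land, protection zones, fixes and isopleths."""
    fig, ax = plt.subplots(figsize=(8, 6))
    if world is not None:
        _draw_geom(ax, world.land, color="0.8", zorder=0)
        for name, zone in world.protection_zones.items():
            _draw_geom(ax, zone, color="tab:green", alpha=0.15)
    for rp in ranges:
        alpha = 0.5 if rp.level <= 0.5 else 0.25
        _draw_geom(ax, rp.geometry, alpha=alpha, color="tab:blue")
    for tr in tracks:
        xy = tr.xy()
        if len(xy):
            ax.plot(xy[:, 0], xy[:, 1], ".-", ms=2, lw=0.4, label=tr.animal_id)
    ax.set_aspect("equal")
    ax.set_xlabel("easting (m)")
    ax.set_ylabel("northing (m)")
    if any(True for _ in tracks):
        ax.legend(fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig, ax
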