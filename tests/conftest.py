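from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from shapely.geometry import box

from seatrack.io_telemetry import Fix, LocClass, Raster, Track
from seatrack.synthetic import World, make_world

TZ = timezone(timedelta(hours=10))
T0 = datetime(2012, 7, 1, 0, 0, tzinfo=TZ)


def mk_fix(
    minutes: float,
    x: float,
    y: float,
    animal_id: str = "a1",
    loc_class: LocClass = LocClass.GPS_SUCCEEDED,
    n_satellites: int = 6,
    residual_error=5.0,
    pdop=2.0,
    t0: datetime = T0,
) -> Fix:
    return Fix(
        animal_id=animal_id,
        timestamp=t0 + timedelta(minutes=minutes),
        x=x,
        y=y,
        loc_class=loc_class,
        n_satellites=n_satellites,
        residual_error=residual_error,
        pdop=pdop,
    )


def mk_track(fixes, species="dugong", schedule_minutes=60, animal_id=None) -> Track:
    aid = animal_id or (fixes[0].animal_id if fixes else "a1")
    return Track(aid, species, list(fixes), schedule_minutes)


def random_track(
    rng: np.random.Generator,
    n: int = 30,
    speed_kmh: float = 3.0,
    dt_minutes: float = 60.0,
    species: str = "turtle",
) -> Track:
    """Slow random walk with randomized quality metadata (for filter oracles)."""
    pos = np.zeros(2)
    fixes = []
    for i in range(n):
        heading = rng.uniform(0, 2 * np.pi)
        step = rng.uniform(0, speed_kmh) * 1000.0 * dt_minutes / 60.0
        pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        fixes.append(
            mk_fix(
                i * dt_minutes,
                pos[0],
                pos[1],
                loc_class=rng.choice(list(LocClass)),
                n_satellites=int(rng.integers(3, 9)),
                residual_error=float(rng.uniform(0, 60)),
                pdop=float(rng.uniform(1, 8)),
            )
        )
    return mk_track(fixes, species=species, schedule_minutes=int(dt_minutes))


@pytest.fixture(scope="session")
def small_world() -> World:
    """Cheap deterministic world shared across tests."""
    return make_world(
        extent=(0.0, 0.0, 20_000.0, 15_000.0),
        coastline_complexity=1.0,
        depth_gradient_m_per_km=1.0,
        n_zones=1,
        seed=7,
        cellsize=250.0,
    )


@pytest.fixture
def flat_world() -> World:
    """Straight-coast world: land is the rectangle y < 2000 m."""
    land = box(0, 0, 20_000, 2_000)
    depth = np.full((10, 20), 3.0)
    bathy = Raster(depth, xll=0.0, yll=0.0, cellsize=1000.0, nodata=-1.0)
    return World(land=land, bathymetry=bathy, protection_zones={}, extent=(0, 0, 20_000, 10_000))
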