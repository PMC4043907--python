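import math

import numpy as np
import pytest

from seatrack.filtering import (
    FilterConfig,
    filter_by_class,
    filter_inland,
    filter_loop_trip,
    filter_overspeed,
    filter_turtle_quality,
    flag_detachment,
    inner_angle,
    speed_between,
)
from seatrack.io_telemetry import LocClass

from .conftest import mk_fix, mk_track, random_track

CFG = FilterConfig()
TURTLE_CFG = FilterConfig(vmax_kmh=9.9, vlp_kmh=2.0)


# --- independent brute-force oracles -----------------------------------------


def oracle_overspeed(fixes, vmax):
    """Forward scan against the last retained fix, repeated to a fixed point."""
    kept = list(fixes)
    while True:
        out = []
        removed = False
        for f in kept:
            if out and speed_between(out[-1], f) > vmax:
                removed = True
                continue
            out.append(f)
        kept = out
        if not removed:
            return kept


def oracle_loop_trip(fixes, cfg):
    """Literal three-clause rule re-evaluated from scratch until stable."""
    kept = list(fixes)
    while True:
        target = None
        for i in range(1, len(kept)):
            if speed_between(kept[i - 1], kept[i]) > cfg.vmax_kmh:
                target = i
                break
        if target is None:
            for i in range(1, len(kept) - 1):
                f = kept[i]
                a, b = kept[i - 1], kept[i + 1]
                if f.n_satellites != 4:
                    continue
                if (a.x, a.y) == (f.x, f.y) or (b.x, b.y) == (f.x, f.y):
                    continue
                if inner_angle((a.x, a.y), (f.x, f.y), (b.x, b.y)) >= cfg.angle_acute_deg:
                    continue
                if speed_between(a, f) > cfg.vlp_kmh or speed_between(f, b) > cfg.vlp_kmh:
                    target = i
                    break
        if target is None:
            return kept
        del kept[target]


# --- class filter -------------------------------------------------------------


def test_all_unresolved_fixes_removed():
    tr = mk_track([mk_fix(60 * i, i, 0, loc_class=LocClass.QFP_UNRESOLVED) for i in range(5)])
    out, rep = filter_by_class(tr, CFG)
    assert len(out) == 0 and rep.n_removed == 5


def test_accurate_classes_all_retained():
    classes = [LocClass.GPS_SUCCEEDED, LocClass.QFP_RESOLVED, LocClass.QFP_UNCERTAIN]
    tr = mk_track([mk_fix(60 * i, i, 0, loc_class=c) for i, c in enumerate(classes)])
    out, rep = filter_by_class(tr, CFG)
    assert len(out) == 3 and rep.n_removed == 0


def test_class_filter_matches_brute_force_scan():
    rng = np.random.default_rng(0)
    tr = random_track(rng, n=60)
    out, _ = filter_by_class(tr, CFG)
    expect = [f for f in tr.fixes if f.loc_class in CFG.allowed_classes]
    assert out.fixes == expect


# --- speed --------------------------------------------------------------------


@pytest.mark.parametrize(
    "dx_m,dt_min,expected",
    [(10_000.0, 60.0, 10.0), (0.0, 45.0, 0.0), (5_000.0, 30.0, 10.0)],
)
def test_speed_between_arithmetic(dx_m, dt_min, expected):
    a, b = mk_fix(0, 0, 0), mk_fix(dt_min, dx_m, 0)
    assert math.isclose(speed_between(a, b), expected)


def test_equal_timestamps_rejected():
    a = mk_fix(0, 0, 0)
    b = mk_fix(0, 100, 0)
    with pytest.raises(ValueError):
        speed_between(a, b)


# --- over-speed ---------------------------------------------------------------


def test_single_spike_removed_neighbours_kept():
    # spike 11 km from both neighbours at 1 h gaps; dugong vmax 10 km/h
    tr = mk_track([mk_fix(0, 0, 0), mk_fix(60, 11_000, 0), mk_fix(120, 0, 0)])
    out, rep = filter_overspeed(tr, CFG)
    assert rep.removed_indices == [1]
    assert [f.x for f in out.fixes] == [0, 0]


def test_slow_track_passes_unchanged():
    tr = mk_track([mk_fix(60 * i, 2000.0 * i, 0) for i in range(10)])
    out, rep = filter_overspeed(tr, CFG)
    assert out.fixes == tr.fixes and rep.n_removed == 0


def test_injected_spikes_are_exactly_the_removed_set():
    rng = np.random.default_rng(42)
    base = random_track(rng, n=40, speed_kmh=2.0)  # well under vmax
    fixes = list(base.fixes)
    spiked = set()
    for idx in rng.choice(np.arange(3, 37), size=4, replace=False):
        f = fixes[idx]
        fixes[idx] = mk_fix(
            (f.timestamp - fixes[0].timestamp).total_seconds() / 60.0,
            f.x + 50_000.0,
            f.y + 50_000.0,
        )
        spiked.add(int(idx))
    tr = mk_track(fixes)
    _, rep = filter_overspeed(tr, CFG)
    assert set(rep.removed_indices) == spiked


def test_overspeed_output_speeds_all_within_vmax():
    rng = np.random.default_rng(7)
    for _ in range(20):
        tr = random_track(rng, n=30, speed_kmh=15.0)
        out, _ = filter_overspeed(tr, CFG)
        for a, b in zip(out.fixes, out.fixes[1:]):
            assert speed_between(a, b) <= CFG.vmax_kmh + 1e-12


def test_overspeed_matches_oracle_and_is_idempotent():
    rng = np.random.default_rng(1)
    for _ in range(50):
        tr = random_track(rng, n=25, speed_kmh=14.0)
        out, rep = filter_overspeed(tr, CFG)
        assert out.fixes == oracle_overspeed(tr.fixes, CFG.vmax_kmh)
        again, rep2 = filter_overspeed(out, CFG)
        assert again.fixes == out.fixes and rep2.n_removed == 0
        assert rep.n_removed + rep.n_retained == rep.n_input


# --- inner angle ----------------------------------------------------------------


@pytest.mark.parametrize(
    "prev,p,nxt,expected",
    [
        ((0, 0), (1, 0), (2, 0), 180.0),  # collinear forward motion
        ((0, 0), (1, 0), (0, 0), 0.0),  # exact backtrack
        ((0, 0), (1, 0), (1, 1), 90.0),  # right-angle dogleg
    ],
)
def test_inner_angle_geometry(prev, p, nxt, expected):
    assert math.isclose(inner_angle(prev, p, nxt), expected, abs_tol=1e-9)


def test_inner_angle_coincident_points_rejected():
    with pytest.raises(ValueError):
        inner_angle((1, 1), (1, 1), (2, 2))


# --- loop-trip filter -----------------------------------------------------------


def test_four_satellite_acute_spike_removed():
    # 4 satellites, acute inner angle, speed-in 2.5 km/h > Vlp 2.0
    tr = mk_track(
        [
            mk_fix(0, 0, 0, n_satellites=6),
            mk_fix(60, 2_500, 0, n_satellites=4),  # out-and-back vertex
            mk_fix(120, 100, 50, n_satellites=6),
        ],
        species="turtle",
    )
    ang = inner_angle((0, 0), (2_500, 0), (100, 50))
    assert ang < 90
    out, rep = filter_loop_trip(tr, TURTLE_CFG)
    assert rep.removed_indices == [1]


def test_five_satellite_spike_retained():
    # same geometry but 5 satellites: clause (a) fails, fix kept
    tr = mk_track(
        [
            mk_fix(0, 0, 0, n_satellites=6),
            mk_fix(60, 2_500, 0, n_satellites=5),
            mk_fix(120, 100, 50, n_satellites=6),
        ],
        species="turtle",
    )
    out, rep = filter_loop_trip(tr, TURTLE_CFG)
    assert rep.n_removed == 0


def test_loop_trip_matches_brute_force_oracle():
    rng = np.random.default_rng(5)
    for _ in range(50):
        tr = random_track(rng, n=25, speed_kmh=5.0)
        out, _ = filter_loop_trip(tr, TURTLE_CFG)
        assert out.fixes == oracle_loop_trip(tr.fixes, TURTLE_CFG)


def test_loop_trip_with_infinite_vlp_degenerates_to_overspeed():
    rng = np.random.default_rng(6)
    cfg = FilterConfig(vmax_kmh=9.9, vlp_kmh=math.inf)
    for _ in range(25):
        tr = random_track(rng, n=25, speed_kmh=14.0)
        a, _ = filter_loop_trip(tr, cfg)
        b, _ = filter_overspeed(tr, FilterConfig(vmax_kmh=9.9))
        assert a.fixes == b.fixes


# --- inland filter --------------------------------------------------------------


def test_inland_fix_removed_coastline_fix_retained(flat_world):
    tr = mk_track(
        [
            mk_fix(0, 5_000, 1_900, animal_id="a1"),  # 100 m inland -> removed
            mk_fix(60, 5_000, 2_000),  # exactly on the coastline -> retained
            mk_fix(120, 5_000, 1_980),  # 20 m inland, within 30 m rule
            mk_fix(180, 5_000, 5_000),  # at sea
        ]
    )
    out, rep = filter_inland(tr, flat_world, CFG)
    assert rep.removed_indices == [0]
    assert len(out) == 3


def test_sea_track_passes_inland_filter(flat_world):
    tr = mk_track([mk_fix(60 * i, 1000.0 * i + 100, 5_000) for i in range(10)])
    out, rep = filter_inland(tr, flat_world, CFG)
    assert out.fixes == tr.fixes


def test_basking_buffer_retains_beach_fixes(flat_world):
    tr = mk_track([mk_fix(0, 5_000, 1_900), mk_fix(60, 5_000, 5_000)], species="turtle")
    strict, _ = filter_inland(tr, flat_world, CFG)
    relaxed, _ = filter_inland(tr, flat_world, FilterConfig(basking_buffer_m=100.0))
    assert len(strict) == 1 and len(relaxed) == 2


def test_missing_land_polygon_rejected():
    tr = mk_track([mk_fix(0, 0, 0)])
    with pytest.raises(ValueError):
        filter_inland(tr, None, CFG)


# --- turtle quality -------------------------------------------------------------


def test_residual_over_threshold_removed():
    tr = mk_track([mk_fix(0, 0, 0, residual_error=31.0, n_satellites=6)], species="turtle")
    _, rep = filter_turtle_quality(tr, TURTLE_CFG)
    assert rep.n_removed == 1


def test_boundary_residual_and_satellites_retained():
    tr = mk_track([mk_fix(0, 0, 0, residual_error=30.0, n_satellites=4)], species="turtle")
    _, rep = filter_turtle_quality(tr, TURTLE_CFG)
    assert rep.n_removed == 0


def test_missing_residual_fails_quality_filter(caplog):
    tr = mk_track([mk_fix(0, 0, 0, residual_error=None)], species="turtle")
    with caplog.at_level("WARNING", logger="seatrack"):
        _, rep = filter_turtle_quality(tr, TURTLE_CFG)
    assert rep.n_removed == 1


def test_quality_filter_matches_brute_force_scan():
    rng = np.random.default_rng(8)
    tr = random_track(rng, n=80)
    out, _ = filter_turtle_quality(tr, TURTLE_CFG)
    expect = [
        f
        for f in tr.fixes
        if f.residual_error is not None
        and f.residual_error <= 30.0
        and f.n_satellites >= 4
    ]
    assert out.fixes == expect


# --- idempotence / ledger property across all filters ----------------------------


@pytest.mark.parametrize("seed", range(5))
def test_filters_are_idempotent_subset_and_reconciled(seed, flat_world):
    rng = np.random.default_rng(seed)
    tr = random_track(rng, n=40, speed_kmh=12.0)
    # shift into the world so the inland filter is exercised
    shifted = [
        mk_fix(
            (f.timestamp - tr.fixes[0].timestamp).total_seconds() / 60.0,
            abs(f.x) % 20_000,
            abs(f.y) % 10_000,
            loc_class=f.loc_class,
            n_satellites=f.n_satellites,
            residual_error=f.residual_error,
            pdop=f.pdop,
        )
        for f in tr.fixes
    ]
    tr = mk_track(shifted, species="turtle")
    filters = [
        lambda t: filter_by_class(t, CFG),
        lambda t: filter_overspeed(t, CFG),
        lambda t: filter_loop_trip(t, TURTLE_CFG),
        lambda t: filter_inland(t, flat_world, CFG),
        lambda t: filter_turtle_quality(t, TURTLE_CFG),
    ]
    for fn in filters:
        out, rep = fn(tr)
        ids = [id(f) for f in tr.fixes]
        assert all(id(f) in ids for f in out.fixes)  # subset, order preserved
        assert [f for f in tr.fixes if id(f) in {id(g) for g in out.fixes}] == out.fixes
        assert rep.n_removed + rep.n_retained == rep.n_input == len(tr.fixes)
        out2, rep2 = fn(out)
        assert out2.fixes == out.fixes and rep2.n_removed == 0


# --- detachment flag -------------------------------------------------------------


def test_stationary_tag_flagged_at_first_fix():
    tr = mk_track([mk_fix(180 * i, 10.0, 5.0) for i in range(41)])  # 5 days at one point
    assert flag_detachment(tr, stationary_days=3.0) == 0


def test_tortuous_track_not_flagged():
    rng = np.random.default_rng(12)
    fixes = []
    pos = np.zeros(2)
    for i in range(60):
        pos = pos + rng.normal(0, 800, 2)
        fixes.append(mk_fix(60 * i, pos[0], pos[1], loc_class=LocClass.QFP_RESOLVED))
    assert flag_detachment(mk_track(fixes), stationary_days=3.0) is None


def test_drift_splice_flagged_near_splice_point():
    rng = np.random.default_rng(13)
    fixes = []
    pos = np.zeros(2)
    for i in range(40):  # tortuous foraging
        pos = pos + rng.normal(0, 700, 2)
        fixes.append(mk_fix(60 * i, pos[0], pos[1], loc_class=LocClass.QFP_RESOLVED))
    splice = len(fixes)
    for j in range(20):  # constant-velocity drift
        pos = pos + np.array([1_000.0, 250.0])
        fixes.append(mk_fix(60 * (40 + j), pos[0], pos[1], loc_class=LocClass.QFP_RESOLVED))
    flag = flag_detachment(mk_track(fixes), straight_steps=12)
    assert flag is not None and abs(flag - splice) <= 2
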