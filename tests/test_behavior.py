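"""Pose derivation, 8-sector turn counting, occupancy, speed and AIM scores."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lidosc import synthgen
from lidosc.behavior import (
    AIM_SUBTYPES,
    arena_square_count,
    compute_speed,
    count_full_turns,
    derive_pose,
    occupancy_fraction,
    score_aims,
    turn_metrics,
)

FPS = 25.0


def make_table(headings_deg, centre=None, likelihood=1.0):
    """Rigid template placed at the given headings (no jitter)."""
    n = len(headings_deg)
    centre = centre if centre is not None else np.zeros((n, 2))
    cols = {}
    cos_h = np.cos(np.radians(headings_deg))
    sin_h = np.sin(np.radians(headings_deg))
    lk = np.broadcast_to(np.asarray(likelihood, dtype=float), (n,))
    for k, part in enumerate(synthgen.BODY_PARTS):
        bx, by = synthgen._BODY_TEMPLATE[k]
        cols[("s", part, "x")] = centre[:, 0] + bx * cos_h - by * sin_h
        cols[("s", part, "y")] = centre[:, 1] + bx * sin_h + by * cos_h
        cols[("s", part, "likelihood")] = lk
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["scorer", "bodyparts", "coords"])
    return df


# brute-force oracle: maximal same-sense runs of sector-boundary crossings,
# floor(run / 8) full turns each (45-degree sectors)


def oracle_turns(heading_deg):
    h = np.asarray(heading_deg, dtype=float)
    h = h[np.isfinite(h)]
    sectors = np.floor(h / 45.0).astype(int) % 8
    steps = (np.diff(sectors) + 4) % 8 - 4
    steps = steps[steps != 0]
    pos = neg = 0
    runs = []
    cur = 0
    for s in steps:
        if cur == 0 or (s > 0) == (cur > 0):
            cur += s
        else:
            runs.append(cur)
            cur = s
    runs.append(cur)
    for r in runs:
        if r > 0:
            pos += r // 8
        else:
            neg += (-r) // 8
    return pos, neg


def machine_counts(heading, fps=FPS):
    turns = count_full_turns(heading, fps)
    c = sum(t.direction == "contralateral" for t in turns)
    i = sum(t.direction == "ipsilateral" for t in turns)
    return c, i


class TestDerivePose:
    def test_template_facing_east(self):
        rec = derive_pose(make_table(np.zeros(10)), FPS)
        assert rec.heading_deg[5] == pytest.approx(0.0, abs=1e-6)
        assert rec.centroid_cm[5] == pytest.approx([6.5 / 7, 0.0], abs=1e-6)

    def test_template_rotated_90(self):
        rec = derive_pose(make_table(np.full(10, 90.0)), FPS)
        assert rec.heading_deg[5] == pytest.approx(90.0, abs=1e-6)

    def test_low_likelihood_frames_excluded(self):
        lk = np.ones(10)
        lk[3] = 0.5
        rec = derive_pose(make_table(np.zeros(10), likelihood=lk), FPS, smooth_frames=1)
        assert not rec.valid[3]
        assert np.isnan(rec.heading_deg[3])
        assert 3 in rec.excluded_frames

    def test_all_frames_excluded_is_an_error(self):
        with pytest.raises(ValueError):
            derive_pose(make_table(np.zeros(10), likelihood=0.5), FPS)

    def test_mostly_excluded_warns(self):
        lk = np.ones(10) * 0.5
        lk[:2] = 1.0
        with pytest.warns(RuntimeWarning):
            derive_pose(make_table(np.zeros(10), likelihood=lk), FPS)

    def test_rigid_rotation_shifts_heading(self):
        base = np.linspace(0, 120, 40)
        rec1 = derive_pose(make_table(base), FPS, smooth_frames=1)
        rec2 = derive_pose(make_table(base + 37.0), FPS, smooth_frames=1)
        diff = (rec2.heading_deg - rec1.heading_deg) % 360.0
        np.testing.assert_allclose(diff, 37.0, atol=1e-6)


class TestTurnCounting:
    def test_two_full_turns_monotone(self):
        heading = np.linspace(0.0, 720.0, 400) % 360.0
        assert machine_counts(heading) == (2, 0)

    def test_incomplete_rotation_resets(self):
        heading = np.concatenate([np.linspace(0, 315, 100), np.linspace(315, 0, 100)])
        assert machine_counts(heading % 360.0) == (0, 0)

    def test_reversal_then_full_turn_other_way(self):
        heading = np.concatenate(
            [np.linspace(0, 200, 60), np.linspace(200, -370, 160)]
        )
        assert machine_counts(heading % 360.0) == (0, 1)

    def test_sector_skips_count_as_traversed(self):
        # 100 deg per frame: skips sectors every frame but still 2 turns
        heading = np.arange(0.0, 730.0, 100.0)
        assert machine_counts(heading % 360.0)[0] == oracle_turns(heading)[0]

    def test_sign_swap_exchanges_directions(self):
        rng = np.random.default_rng(8)
        heading = np.cumsum(rng.normal(3.0, 10.0, 500))
        c, i = machine_counts(heading % 360.0)
        c2, i2 = machine_counts((-heading) % 360.0)
        assert (c, i) == (i2, c2)

    def test_long_gap_resets_count(self):
        heading = np.linspace(0.0, 350.0, 100)
        with_gap = np.concatenate([heading[:50], np.full(30, np.nan), heading[50:]])
        # 30 missing frames > 1 s at 25 fps: rotation must not complete
        assert machine_counts(with_gap % 360.0) == (0, 0)
        short_gap = np.concatenate([heading[:50], np.full(10, np.nan), heading[50:]])
        extended = np.concatenate([short_gap, np.linspace(350, 400, 20)])
        assert machine_counts(extended % 360.0) == (1, 0)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_random_series(self, seed):
        rng = np.random.default_rng(seed)
        # piecewise-monotone: random segments of random drift and sign
        parts = []
        for _ in range(rng.integers(2, 6)):
            drift = rng.uniform(5.0, 80.0) * rng.choice([-1, 1])
            parts.append(np.full(rng.integers(10, 80), drift))
        heading = np.cumsum(np.concatenate(parts)) + rng.uniform(0, 360)
        assert machine_counts(heading % 360.0) == oracle_turns(heading)


class TestTurnMetrics:
    def test_circular_path_distance(self):
        # one full turn on a radius-10 circle: distance ~ 2*pi*10 (+-2%)
        n = 251
        ang = np.linspace(0, 360, n)
        centre = 10.0 * np.column_stack(
            [np.cos(np.radians(ang - 90)), np.sin(np.radians(ang - 90))]
        )
        table = make_table(ang % 360.0, centre=centre)
        rec = derive_pose(table, FPS, smooth_frames=1)
        turns = count_full_turns(rec.heading_deg, FPS)
        assert len(turns) == 1
        turns = turn_metrics(turns, centre, FPS)
        assert turns[0].distance_cm == pytest.approx(2 * math.pi * 10, rel=0.02)
        assert turns[0].duration_s == pytest.approx((n - 1) / FPS, abs=0.2)

    def test_pivot_turn_travels_nowhere(self):
        ang = np.linspace(0, 400, 300)
        table = make_table(ang % 360.0)
        rec = derive_pose(table, FPS, smooth_frames=1)
        turns = turn_metrics(
            count_full_turns(rec.heading_deg, FPS), np.zeros((300, 2)), FPS
        )
        assert turns and turns[0].distance_cm == pytest.approx(0.0, abs=1e-9)

    def test_duration_from_frame_count(self):
        ang = np.linspace(0, 368, 251)  # completes within ~10 s at 25 fps
        turns = count_full_turns(ang % 360.0, FPS)
        assert turns[0].duration_s == pytest.approx(10.0, abs=0.5)


class TestOccupancy:
    def test_total_square_count_oracle(self):
        # enumeration oracle for the 55-cm circle with center-inclusion rule
        r = 27.5
        count = sum(
            1
            for i in range(-30, 30)
            for j in range(-30, 30)
            if (i + 0.5) ** 2 + (j + 0.5) ** 2 < r**2
        )
        assert arena_square_count(55.0) == count
        assert abs(count - math.pi * r**2) / (math.pi * r**2) < 0.02

    def test_stationary_animal_single_square(self):
        centroid = np.tile([3.2, -4.7], (1500, 1))
        occ = occupancy_fraction(centroid, FPS)
        assert occ.fraction[0] == pytest.approx(1 / occ.total_squares)

    def test_full_coverage_is_one(self):
        r = 27.5
        centres = np.array(
            [
                [i + 0.5, j + 0.5]
                for i in range(-28, 28)
                for j in range(-28, 28)
                if (i + 0.5) ** 2 + (j + 0.5) ** 2 < r**2
            ]
        )
        occ = occupancy_fraction(centres, fps=len(centres) / 60.0)
        assert occ.fraction[0] == pytest.approx(1.0)

    def test_superset_path_covers_at_least_as_much(self):
        rng = np.random.default_rng(9)
        path = rng.uniform(-20, 20, (1500, 2))
        frac1 = occupancy_fraction(path, FPS).fraction[0]
        path2 = path.copy()
        path2[:200] = rng.uniform(-25, 25, (200, 2))  # perturbed superset window
        both = np.vstack([path, path2])
        frac2 = occupancy_fraction(both, fps=len(both) / 60.0).fraction[0]
        assert frac2 >= frac1


class TestSpeed:
    def test_uniform_motion(self):
        t = np.arange(0, 20, 1 / FPS)
        centroid = np.column_stack([5.0 * t, np.zeros_like(t)])
        speed = compute_speed(centroid, FPS)
        np.testing.assert_allclose(speed, 5.0, atol=1e-9)

    def test_stationary(self):
        speed = compute_speed(np.zeros((100, 2)), FPS)
        np.testing.assert_allclose(speed, 0.0)

    def test_circular_motion_chord_formula(self):
        r, period = 12.0, 8.0
        t = np.arange(0, 30, 1 / FPS)
        ang = 2 * np.pi * t / period
        centroid = r * np.column_stack([np.cos(ang), np.sin(ang)])
        speed = compute_speed(centroid, FPS)
        expected = 2 * r * math.sin(math.pi / period)
        np.testing.assert_allclose(speed, expected, rtol=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_speed(np.zeros((10, 2)), FPS)


def make_sheet(rows):
    return pd.DataFrame(rows, columns=["period_min", "subtype", "severity", "amplitude"])


class TestAIMScoring:
    def test_composite_and_global(self):
        rows = [
            (5, "axial", 2, 2),
            (5, "limb", 3, 2),
            (5, "orolingual", 1, 1),
        ]
        series = score_aims(make_sheet(rows))
        assert series.composite.loc[5].tolist() == [4, 6, 1]
        assert series.global_score.loc[5] == 11

    def test_maximum_period(self):
        rows = [(10, s, 4, 4) for s in AIM_SUBTYPES]
        series = score_aims(make_sheet(rows))
        assert series.global_score.loc[10] == 48

    def test_zero_sheet(self):
        rows = [(m, s, 0, 0) for m in (5, 10) for s in AIM_SUBTYPES]
        series = score_aims(make_sheet(rows))
        assert series.session_total == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_aims(make_sheet([(5, "axial", 5, 2)]))

    def test_peak_window_sum(self):
        grid = synthgen.aim_monitoring_grid(180)
        rows = [(m, s, 1, 1) for m in grid for s in AIM_SUBTYPES]
        series = score_aims(make_sheet(rows))
        # L-DOPA window 40-80 min inclusive: periods 40,50,60,70,80 -> 5*3
        assert series.peak_score("L-DOPA") == 15
        assert series.peak_score("SKF82958") == 15  # 20,30,40,50,60
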