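"""Food-zone geometry, bout segmentation, and behavioral metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import boutometry as bm
from boutometry.microstructure import nearest_rank_quantile

from conftest import make_session


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def bruteforce_quantile(values, q):
    """Nearest-rank quantile by explicit rank arithmetic."""
    ordered = sorted(values)
    rank = max(1, math.ceil(q * len(ordered)))
    return ordered[rank - 1]


def bruteforce_segment(times, threshold, min_licks):
    """O(n^2)-style splitter: test every adjacent pair as a split point."""
    bouts, run = [], []
    for t in times:
        if run and t - run[-1] > threshold:
            bouts.append(run)
            run = []
        run.append(t)
    if run:
        bouts.append(run)
    kept = [b for b in bouts if len(b) >= min_licks]
    discarded = sum(len(b) for b in bouts if len(b) < min_licks)
    return kept, discarded


def make_pose(distances=None, mouth=None, n=None, spout=(0.0, 0.0), fps=30.0):
    if mouth is None:
        mouth = np.column_stack([np.asarray(distances, float), np.zeros(len(distances))])
    n = len(mouth)
    t = np.arange(n) / fps
    tail = mouth + np.array([1.0, 0.0])
    return bm.PoseTrack(frame_times_s=t, mouth_xy=mouth, tailbase_xy=tail,
                        spout_xy=np.asarray(spout, float))


# ---------------------------------------------------------------------------
# food zone
# ---------------------------------------------------------------------------


class TestFoodZone:
    def test_constant_body_length_radius(self):
        mouth = np.zeros((100, 2))
        tail = np.tile([8.0, 0.0], (100, 1))
        pose = bm.PoseTrack(np.arange(100) / 30.0, mouth, tail, np.zeros(2))
        assert bm.food_zone_radius(pose, 0.95) == pytest.approx(8.0)

    def test_nearest_rank_on_small_sample(self):
        mouth = np.zeros((5, 2))
        tail = np.column_stack([[2.0, 4.0, 6.0, 8.0, 10.0], np.zeros(5)])
        pose = bm.PoseTrack(np.arange(5) / 30.0, mouth, tail, np.zeros(2))
        assert bm.food_zone_radius(pose, 0.95) == pytest.approx(10.0)

    def test_empty_track_rejected(self):
        with pytest.raises(bm.ValidationError):
            nearest_rank_quantile([], 0.95)

    @given(
        st.lists(st.floats(0.1, 50.0), min_size=1, max_size=40),
        st.floats(0.01, 1.0),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_quantile_matches_bruteforce(self, values, q):
        assert nearest_rank_quantile(values, q) == pytest.approx(
            bruteforce_quantile(values, q)
        )

    def test_single_dwell_interval(self):
        # inside the zone exactly for frames [300, 600) of a 30-fps track
        d = np.full(900, 10.0)
        d[300:600] = 1.0
        intervals = bm.food_zone_times(make_pose(distances=d), radius_cm=5.0)
        assert len(intervals) == 1
        assert intervals[0].enter_s == pytest.approx(300 / 30.0)
        assert intervals[0].duration_s == pytest.approx(10.0)
        assert not intervals[0].at_edge

    def test_never_inside(self):
        d = np.full(100, 10.0)
        assert bm.food_zone_times(make_pose(distances=d), radius_cm=5.0) == []

    def test_alternating_frames_span_one_interframe_interval(self):
        d = np.tile([1.0, 10.0], 50)
        intervals = bm.food_zone_times(make_pose(distances=d), radius_cm=5.0)
        assert len(intervals) == 50
        for iv in intervals[:-1]:
            assert iv.duration_s == pytest.approx(1 / 30.0)

    def test_total_dwell_monotone_in_radius(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 20, 500)
        pose = make_pose(distances=d)
        totals = []
        for r in [2.0, 5.0, 10.0, 20.0]:
            ivs = bm.food_zone_times(pose, r)
            for a, b in zip(ivs, ivs[1:]):
                assert a.exit_s <= b.enter_s  # disjoint, ordered
            totals.append(sum(iv.duration_s for iv in ivs))
        assert totals == sorted(totals)


def test_derive_food_zone_params_composes_the_workflow():
    rng = np.random.default_rng(1)
    d = np.where(rng.random(600) < 0.4, 2.0, 15.0)  # dwell runs near the spout
    mouth = np.column_stack([d, np.zeros(600)])
    pose = bm.PoseTrack(
        frame_times_s=np.arange(600) / 30.0,
        mouth_xy=mouth,
        tailbase_xy=mouth + np.array([8.0, 0.0]),  # constant 8-cm body length
        spout_xy=np.zeros(2),
    )
    params = bm.derive_food_zone_params(pose)
    assert params.radius_cm == pytest.approx(
        bm.food_zone_radius(pose, 0.95)
    )
    durations = [iv.duration_s for iv in params.fzt_intervals]
    assert params.ili_threshold_s == pytest.approx(bm.ili_threshold(durations, 0.10))


class TestIliThreshold:
    def test_lower_decile_of_fzt(self):
        durations = [5, 10, 15, 20, 25, 30, 35, 40, 45, 50]
        assert bm.ili_threshold(durations, 0.10) == pytest.approx(5.0)

    def test_degenerate_sample(self):
        assert bm.ili_threshold([7.0, 7.0, 7.0], 0.10) == pytest.approx(7.0)

    def test_empty_rejected(self):
        with pytest.raises(bm.ValidationError):
            bm.ili_threshold([], 0.10)

    @given(st.lists(st.floats(0.1, 100.0), min_size=3, max_size=30))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_monotone_in_q(self, durations):
        qs = [0.1, 0.3, 0.5, 0.7, 0.9]
        vals = [bm.ili_threshold(durations, q) for q in qs]
        assert vals == sorted(vals)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


class TestSegmentBouts:
    def test_hand_checkable_example(self):
        session = make_session([0.0, 1.0, 2.0, 10.0, 11.0])
        table = bm.segment_bouts(session, ili_threshold_s=5.0, min_licks=1)
        assert table.n_bouts == 2
        row0, row1 = table.frame.iloc[0], table.frame.iloc[1]
        assert (row0.start_s, row0.end_s, row0.n_licks) == (0.0, 2.0, 3)
        assert row0.duration_s == pytest.approx(2.0)
        assert (row1.start_s, row1.end_s, row1.n_licks) == (10.0, 11.0, 2)

    def test_no_licks_empty_table(self):
        table = bm.segment_bouts(make_session([]), ili_threshold_s=5.0)
        assert table.n_bouts == 0
        assert table.n_discarded_licks == 0

    def test_ili_exactly_at_threshold_continues_bout(self):
        session = make_session([0.0, 5.0, 10.0])
        table = bm.segment_bouts(session, ili_threshold_s=5.0)
        assert table.n_bouts == 1
        assert table.frame.iloc[0].n_licks == 3

    def test_min_licks_discard_tally(self):
        session = make_session([0.0, 0.1, 20.0, 40.0, 40.1, 40.2])
        table = bm.segment_bouts(session, ili_threshold_s=5.0, min_licks=2)
        assert table.n_bouts == 2
        assert table.n_discarded_licks == 1
        assert table.frame["n_licks"].sum() + table.n_discarded_licks == 6

    @given(
        st.lists(st.floats(0.0, 100.0), min_size=0, max_size=50, unique=True),
        st.floats(0.05, 10.0),
        st.integers(1, 4),
    )
    @settings(deadline=None, max_examples=120, derandomize=True)
    def test_matches_bruteforce_splitter(self, times, threshold, min_licks):
        times = sorted(times)
        session = make_session(times, session_length=120.0)
        table = bm.segment_bouts(session, threshold, min_licks=min_licks)
        expected, discarded = bruteforce_segment(times, threshold, min_licks)
        assert table.n_bouts == len(expected)
        assert table.n_discarded_licks == discarded
        for row, run in zip(table.frame.itertuples(index=False), expected):
            assert row.start_s == pytest.approx(run[0])
            assert row.end_s == pytest.approx(run[-1])
            assert row.n_licks == len(run)
        # conservation of licks under any threshold / min_licks
        assert table.frame["n_licks"].sum() + table.n_discarded_licks == len(times)


class TestFundamentalLickInterval:
    def test_pure_rhythm(self):
        times = np.arange(50) * 0.125
        assert bm.fundamental_lick_interval(make_session(times)) == pytest.approx(0.125)

    def test_tie_breaks_to_smallest_bin(self):
        # equal counts at 0.10 and 0.30: the smaller bin center wins
        times = [0.0]
        for _ in range(10):
            times.append(times[-1] + 0.105)
        for _ in range(10):
            times.append(times[-1] + 0.305)
        got = bm.fundamental_lick_interval(make_session(times))
        assert got == pytest.approx(0.105)

    def test_requires_two_licks(self):
        with pytest.raises(bm.ValidationError):
            bm.fundamental_lick_interval(make_session([1.0]))

    def test_recovered_from_simulated_session(self, bundle):
        got = bm.fundamental_lick_interval(bundle.session)
        assert abs(got - 0.125) <= 0.01  # within one 10-ms bin


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------


def brute_block_of(t, schedule):
    for i, (s, e, _) in enumerate([tuple(b) for b in schedule]):
        if s <= t < e:
            return i
    raise AssertionError("outside schedule")


class TestAssignBlocks:
    def test_boundary_spanning_bout(self):
        schedule = bm.build_schedule(240.0, 120.0, "high", ("high", "low"))
        session = make_session([119.0, 121.0], session_length=240.0)
        table = bm.segment_bouts(session, ili_threshold_s=5.0)
        table = bm.assign_blocks(table, schedule)
        row = table.frame.iloc[0]
        assert row.block_index == 0 and row.block_label == "high"
        assert bool(row.spans_block)

    def test_contained_bout(self):
        schedule = bm.build_schedule(240.0, 120.0, "high", ("high", "low"))
        session = make_session([0.0, 5.0], session_length=240.0)
        table = bm.assign_blocks(bm.segment_bouts(session, 5.0), schedule)
        row = table.frame.iloc[0]
        assert row.block_index == 0 and not bool(row.spans_block)

    def test_bout_outside_session_rejected(self):
        schedule = bm.build_schedule(120.0, 120.0, "high", ("high", "low"))
        import pandas as pd

        frame = pd.DataFrame(
            [{"start_s": 119.0, "end_s": 125.0, "duration_s": 6.0, "n_licks": 3,
              "block_index": -1, "block_label": "", "spans_block": False}]
        )
        with pytest.raises(bm.ValidationError):
            bm.assign_blocks(bm.BoutTable(frame=frame), schedule)

    def test_random_bouts_match_bruteforce_lookup(self):
        schedule = bm.build_schedule(1200.0, 120.0, "high", ("high", "low"))
        rng = np.random.default_rng(5)
        starts, ends = [], []
        cursor = 0.0
        for _ in range(200):
            s = cursor + rng.uniform(0.02, 2.0)
            e = min(s + rng.uniform(0.0, 4.0), 1199.9)
            if s >= 1199.8:
                break
            starts.append(s)
            ends.append(max(e, s))
            cursor = ends[-1]
        starts, ends = np.array(starts), np.array(ends)
        import pandas as pd

        frame = pd.DataFrame(
            {"start_s": starts, "end_s": ends, "duration_s": ends - starts,
             "n_licks": 2, "block_index": -1, "block_label": "", "spans_block": False}
        )
        table = bm.assign_blocks(bm.BoutTable(frame=frame), schedule)
        for row in table.frame.itertuples(index=False):
            i = brute_block_of(row.start_s, schedule)
            assert row.block_index == i
            assert row.spans_block == (brute_block_of(row.end_s, schedule) != i)


class TestLicksPerBlock:
    def test_silent_condition_reported_missing_not_zero(self):
        schedule = bm.build_schedule(480.0, 120.0, "OFF", ("OFF", "ON"))
        session = make_session([130.0, 131.0, 370.0], session_length=480.0)  # ON blocks only
        frame, means = bm.licks_per_block(session, schedule)
        assert np.isnan(means["OFF"])
        assert means["ON"] == pytest.approx(1.5)

    def test_uniform_licking_is_symmetric(self):
        schedule = bm.build_schedule(480.0, 120.0, "OFF", ("OFF", "ON"))
        session = make_session(np.arange(0.5, 480.0, 1.0), session_length=480.0)
        _, means = bm.licks_per_block(session, schedule)
        assert means["ON"] == pytest.approx(means["OFF"])

    def test_matches_bruteforce_count(self):
        schedule = bm.build_schedule(600.0, 120.0, "high", ("high", "low"))
        rng = np.random.default_rng(9)
        times = np.sort(rng.uniform(0, 599.9, 300))
        times = np.unique(times)
        session = make_session(times, session_length=600.0)
        frame, _ = bm.licks_per_block(session, schedule)
        for i, (s, e, _label) in enumerate(tuple(b) for b in schedule):
            expected = int(np.sum((times >= s) & (times < e)))
            assert frame.loc[i, "n_licks"] == expected


class TestLickRateProfile:
    def test_three_second_bout_bins(self):
        times = np.arange(0, 3.0, 0.125) + 10.0  # 8 licks/s for 3 s
        session = make_session(times, session_length=120.0)
        table = bm.segment_bouts(session, ili_threshold_s=1.0)
        profile = bm.bout_lick_rate_profile(table, session)
        np.testing.assert_allclose(profile.counts[0, :3], [8, 8, 8])
        assert np.isnan(profile.counts[0, 3:]).all()

    def test_empty_table(self):
        session = make_session([])
        table = bm.segment_bouts(session, ili_threshold_s=1.0)
        profile = bm.bout_lick_rate_profile(table, session)
        assert profile.counts.shape == (0, 20)

    def test_high_palatability_profile_exceeds_low_in_late_bins(self):
        cfg = bm.SessionConfig(session_length_s=1200.0, seed=21)
        params = bm.SimParams(seed=21, bout_rate_per_min=2.0)
        session, truth = bm.simulate_licks(cfg, params)
        schedule = bm.build_schedule(1200.0, 120.0, "high", ("high", "low"))
        table = bm.assign_blocks(truth.bout_table(), schedule)
        frame = table.frame
        hi = bm.BoutTable(frame=frame[frame.block_label == "high"].reset_index(drop=True))
        lo = bm.BoutTable(frame=frame[frame.block_label == "low"].reset_index(drop=True))
        p_hi = bm.bout_lick_rate_profile(hi, session)
        p_lo = bm.bout_lick_rate_profile(lo, session)
        # longer high-palatability bouts keep more late bins populated
        n_hi = np.sum(~np.isnan(p_hi.counts), axis=0)
        n_lo = np.sum(~np.isnan(p_lo.counts), axis=0)
        late = slice(5, 20)
        assert n_hi[late].sum() / max(1, p_hi.n_bouts) > n_lo[late].sum() / max(1, p_lo.n_bouts)


class TestEnergyIntake:
    def test_full_strength_density(self, config_short):
        kcal = bm.energy_intake(config_short, volume_ml=237.0, dilution=1.0)
        assert kcal == pytest.approx(220.0)

    def test_delivery_rule(self, config_short):
        assert bm.delivered_volume_ul(config_short, 3) == pytest.approx(3.0)
        assert bm.delivered_volume_ul(config_short, 5) == pytest.approx(3.0)
        assert bm.delivered_volume_ul(config_short, 6) == pytest.approx(6.0)

    def test_zero_licks(self, config_short):
        assert bm.energy_intake(config_short, n_licks=0) == 0.0

    def test_homogeneous_in_volume(self, config_short):
        e1 = bm.energy_intake(config_short, volume_ml=1.7, dilution=0.2)
        e2 = bm.energy_intake(config_short, volume_ml=3.4, dilution=0.2)
        assert e2 == pytest.approx(2 * e1)

    def test_negative_rejected(self, config_short):
        with pytest.raises(bm.ValidationError):
            bm.energy_intake(config_short, n_licks=-1)
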