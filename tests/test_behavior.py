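import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from usv44.behavior import (
    FreezeParams,
    bin_linkage,
    call_nested_freezing,
    freezing_percent,
    score_freezing,
)
from usv44.calltable_io import CallType, MotionSeries, SessionMeta
from usv44.classify import classify_table
from tests.conftest import make_record


def motion_from_runs(runs, low=0.0, high=100.0):
    """Build a motion series from (n_frames, is_still) run specs."""
    parts = [np.full(n, low if still else high) for n, still in runs]
    return MotionSeries(values=np.concatenate(parts), frame_rate=30.0)


class TestScoreFreezing:
    def test_all_still_all_frozen(self):
        mask = score_freezing(MotionSeries(values=np.zeros(300)))
        assert mask.all()

    def test_29_frames_not_enough(self):
        motion = motion_from_runs([(10, False), (29, True), (10, False)])
        mask = score_freezing(motion)
        assert not mask.any()

    def test_exactly_30_frames_frozen(self):
        motion = motion_from_runs([(10, False), (30, True), (10, False)])
        mask = score_freezing(motion)
        assert mask.sum() == 30

    def test_runs_40_and_20_exactly_40_frozen(self):
        # hand run-length oracle: only the 40-frame run passes the minimum
        motion = motion_from_runs([(40, True), (5, False), (20, True)])
        mask = score_freezing(motion)
        assert mask.sum() == 40
        assert mask[:40].all() and not mask[45:].any()

    def test_threshold_is_strict(self):
        motion = MotionSeries(values=np.full(60, 18.0))  # exactly at threshold: moving
        assert not score_freezing(motion).any()
        motion = MotionSeries(values=np.full(60, 17.9))
        assert score_freezing(motion).all()

    @settings(max_examples=30, deadline=None)
    @given(
        values=st.lists(st.floats(min_value=0, max_value=50, allow_nan=False), min_size=40, max_size=120),
        bump=st.floats(min_value=0.0, max_value=20.0),
    )
    def test_threshold_monotonicity(self, values, bump):
        """Raising the threshold never unfreezes a frame."""
        motion = MotionSeries(values=np.array(values))
        lo = score_freezing(motion, FreezeParams(motion_threshold=18.0))
        hi = score_freezing(motion, FreezeParams(motion_threshold=18.0 + bump))
        assert np.all(hi[lo])

    @settings(max_examples=30, deadline=None)
    @given(
        values=st.lists(st.floats(min_value=0, max_value=50, allow_nan=False), min_size=40, max_size=120),
        fewer=st.integers(min_value=1, max_value=29),
    )
    def test_min_frames_monotonicity(self, values, fewer):
        """Decreasing min_frames never decreases the frozen-frame count."""
        motion = MotionSeries(values=np.array(values))
        base = score_freezing(motion, FreezeParams(min_frames=30))
        relaxed = score_freezing(motion, FreezeParams(min_frames=fewer))
        assert relaxed.sum() >= base.sum()
        assert np.all(relaxed[base])


class TestFreezingPercent:
    def test_bounds_and_concatenation(self):
        rng = np.random.default_rng(0)
        mask = rng.random(900) < 0.5
        p_all = freezing_percent(mask, 0.0, 30.0, 30.0)
        p1 = freezing_percent(mask, 0.0, 10.0, 30.0)
        p2 = freezing_percent(mask, 10.0, 20.0, 30.0)
        p3 = freezing_percent(mask, 20.0, 30.0, 30.0)
        assert 0.0 <= p_all <= 100.0
        # frame-weighted mean over a disjoint partition reproduces the whole
        assert p_all == pytest.approx((p1 + p2 + p3) / 3)

    def test_empty_window_error(self):
        with pytest.raises(ValueError):
            freezing_percent(np.ones(30, dtype=bool), 5.0, 5.0, 30.0)


def _mask_for(meta, frozen=True):
    n = int(meta.session_length * meta.frame_rate)
    return np.full(n, frozen)


class TestBinLinkage:
    def make_meta(self, session_length=400.0, shock_times=(310.0,)):
        return SessionMeta(
            rat_id="r", session_id="s", shock_times=shock_times, session_length=session_length
        )

    def test_only_long22_fully_frozen(self):
        meta = self.make_meta()
        records = [make_record(onset=315.0, call_type=CallType.LONG22)]
        report = bin_linkage(records, _mask_for(meta), meta)
        bins = {b.start: b for b in report.bins}
        assert bins[310.0].category == "only_long22"
        assert bins[310.0].freezing == pytest.approx(100.0)

    def test_mixed_bin(self):
        meta = self.make_meta()
        records = [
            make_record(call_id="a", onset=315.0, call_type=CallType.LONG22),
            make_record(call_id="b", onset=316.0, call_type=CallType.FIFTY),
        ]
        report = bin_linkage(records, _mask_for(meta), meta)
        assert {b.category for b in report.bins if b.start == 310.0} == {"mixed"}

    def test_baseline_and_no_calls_windows(self):
        meta = self.make_meta(session_length=400.0, shock_times=(310.0,))
        report = bin_linkage([], _mask_for(meta, frozen=False), meta)
        cats = {b.start: b.category for b in report.bins}
        assert cats[0.0] == "baseline"
        assert cats[290.0] == "baseline"
        assert 300.0 not in cats  # silent, after baseline, before first shock
        assert cats[310.0] == "no_calls"
        assert all(v == pytest.approx(0.0) for v in (b.freezing for b in report.bins))

    def test_baseline_truncated_at_early_first_shock(self):
        meta = self.make_meta(session_length=400.0, shock_times=(100.0,))
        report = bin_linkage([], _mask_for(meta), meta)
        cats = {b.start: b.category for b in report.bins}
        assert cats[90.0] == "baseline"
        assert cats[100.0] == "no_calls"

    def test_onset_decides_bin_membership(self):
        meta = self.make_meta()
        # call starts at 319.5 and spills into the next bin; onset rules
        records = [make_record(onset=319.5, duration=2.0, call_type=CallType.FORTYFOUR)]
        report = bin_linkage(records, _mask_for(meta), meta)
        cats = {b.start: b.category for b in report.bins}
        assert cats[310.0] == "only_fortyfour"
        assert cats[320.0] == "no_calls"

    def test_short_mask_error(self):
        meta = self.make_meta()
        with pytest.raises(ValueError, match="mask"):
            bin_linkage([], np.ones(100, dtype=bool), meta)

    def test_planted_freezing_ordering_recovered(self, default_cohort):
        means = {"only_fortyfour": [], "no_calls": [], "baseline": []}
        for meta, records, motion in default_cohort.sessions:
            labeled, _ = classify_table(records)
            mask = score_freezing(motion)
            report = bin_linkage(sorted(labeled, key=lambda r: r.onset), mask, meta)
            for cat, val in report.freezing_by_category().items():
                if cat in means:
                    means[cat].append(val)
        assert np.mean(means["only_fortyfour"]) > np.mean(means["no_calls"])
        assert np.mean(means["no_calls"]) < np.mean(means["only_fortyfour"]) - 10.0


class TestCallNestedFreezing:
    def test_equal_durations_full_spans(self):
        motion = MotionSeries(values=np.zeros(600))
        a = make_record(call_id="a", onset=5.0, duration=0.5)
        b = make_record(call_id="b", onset=10.0, duration=0.5)
        pa, pb = call_nested_freezing(a, b, motion, FreezeParams(min_frames=5))
        assert pa == pytest.approx(100.0) and pb == pytest.approx(100.0)

    def test_centered_window_on_longer_call(self):
        # 0.3 s and 0.9 s calls: both windows are 0.3 s; the longer call's
        # window starts 0.3 s after its onset (centered)
        fps = 30.0
        n = int(20 * fps)
        values = np.full(n, 100.0)
        # freeze exactly the longer call's centered middle third [10.3, 10.6)
        values[int(10.3 * fps) : int(10.6 * fps)] = 0.0
        # and the shorter call's whole span [5.0, 5.3)
        values[int(5.0 * fps) : int(5.3 * fps)] = 0.0
        motion = MotionSeries(values=values, frame_rate=fps)
        short = make_record(call_id="s", onset=5.0, duration=0.3)
        longer = make_record(call_id="l", onset=10.0, duration=0.9)
        ps, pl = call_nested_freezing(short, longer, motion, FreezeParams(min_frames=3))
        assert ps == pytest.approx(100.0)
        assert pl == pytest.approx(100.0)

    def test_fully_frozen_session(self):
        motion = MotionSeries(values=np.zeros(600))
        a = make_record(call_id="a", onset=2.0, duration=0.6)
        b = make_record(call_id="b", onset=8.0, duration=1.0)
        pa, pb = call_nested_freezing(a, b, motion, FreezeParams(min_frames=10))
        assert pa == pytest.approx(100.0) and pb == pytest.approx(100.0)

    def test_call_shorter_than_window_floor_error(self):
        motion = MotionSeries(values=np.zeros(600))
        a = make_record(call_id="a", onset=2.0, duration=0.05)
        b = make_record(call_id="b", onset=8.0, duration=1.0)
        with pytest.raises(ValueError, match="shorter"):
            call_nested_freezing(a, b, motion, FreezeParams(min_frames=3))

    def test_reduced_min_frames_recomputed_globally(self):
        # a 10-frame stillness inside the call freezes at min_frames=5 but
        # not at the default 30
        fps = 30.0
        values = np.full(300, 100.0)
        values[150:160] = 0.0
        motion = MotionSeries(values=values, frame_rate=fps)
        a = make_record(call_id="a", onset=5.0, duration=10 / fps)
        b = make_record(call_id="b", onset=2.0, duration=10 / fps)
        pa, _ = call_nested_freezing(a, b, motion, FreezeParams(min_frames=5))
        assert pa == pytest.approx(100.0)
        with pytest.raises(ValueError):
            # default min_frames implies a 1 s duration floor > both calls
            call_nested_freezing(a, b, motion, FreezeParams(min_frames=30))
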