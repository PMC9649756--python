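"""Run-length burst detection: step probabilities, thresholds, segmentation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from granuletrace import (
    compute_step_probabilities,
    compute_thresholds,
    detect_bursts,
    inter_event_intervals,
    segment_trace,
)
from granuletrace.bursts import NEGATIVE, POSITIVE, UNCLASSIFIED, BurstEvent


class TestStepProbabilities:
    def test_strictly_increasing(self):
        p_inc, p_dec, n = compute_step_probabilities(np.arange(10.0))
        assert (p_inc, p_dec, n) == (1.0, 0.0, 9)

    def test_hand_counted_mixed_series(self):
        # increments [1, 0, -1, 2]: zeros count in the total only
        p_inc, p_dec, n = compute_step_probabilities(np.array([0.0, 1.0, 1.0, 0.0, 2.0]))
        assert n == 4
        assert p_inc == 0.5
        assert p_dec == 0.25

    def test_alternating_series_is_symmetric(self):
        s = np.append(np.array([0.0, 1.0] * 50), 0.0)  # 50 ups, 50 downs
        p_inc, p_dec, _ = compute_step_probabilities(s)
        assert p_inc == p_dec == pytest.approx(0.5)

    def test_nan_increments_excluded(self):
        s = np.array([0.0, 1.0, np.nan, 2.0, 3.0])
        p_inc, p_dec, n = compute_step_probabilities(s)
        assert n == 2  # the two NaN-adjacent increments are dropped
        assert p_inc == 1.0


class TestThresholds:
    def test_symmetric_noise_threshold_enforced_to_span(self):
        th = compute_thresholds(0.5, 0.5, min_span=13)
        assert th.m_inc_raw == pytest.approx(10.0)
        assert th.m_inc == 13 and th.m_dec == 13

    def test_high_probability_threshold_unchanged(self):
        p = 2.0 ** (-10.0 / 20.0)  # closed form: m = 20
        th = compute_thresholds(p, 0.5, min_span=13)
        assert th.m_inc_raw == pytest.approx(20.0)
        assert th.m_inc == 20

    def test_quarter_probability_raised_to_minimum(self):
        th = compute_thresholds(0.25, 0.25, min_span=13)
        assert th.m_inc_raw == pytest.approx(5.0)  # log2(0.25) = -2
        assert th.m_inc == 13

    def test_zero_probability_gives_infinite_threshold(self):
        th = compute_thresholds(0.0, 0.5, min_span=13)
        assert math.isinf(th.m_inc)
        assert th.m_dec == 13

    def test_degenerate_probability_one_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            th = compute_thresholds(1.0, 0.5, min_span=13)
        assert th.m_inc == 13

    def test_alpha_knob_changes_threshold(self):
        strict = compute_thresholds(0.7071067811865476, 0.5, alpha=2.0**-20)
        assert strict.m_inc == pytest.approx(40.0)


def _flat_with_ramp(ramp_increments, height=100.0, n=120, start=40):
    s = np.zeros(n)
    step = height / ramp_increments
    for k in range(ramp_increments):
        s[start + 1 + k :] += step
    return s


class TestSegmentation:
    def test_constant_trace_has_no_events(self):
        th = compute_thresholds(0.5, 0.5)
        assert segment_trace(np.full(100, 5.0), th, 10.0) == []

    def test_suprathreshold_ramp_is_one_positive_event(self):
        s = _flat_with_ramp(20, height=100.0)
        th = compute_thresholds(0.5, 0.5)  # m = 13
        events = segment_trace(s, th, 10.0)
        assert len(events) == 1
        (ev,) = events
        assert ev.direction == POSITIVE
        assert ev.amplitude == pytest.approx(100.0)
        assert ev.duration_s == pytest.approx(20 * 10.0)
        assert ev.end_index - ev.start_index == 20

    def test_subthreshold_ramp_yields_nothing(self):
        s = _flat_with_ramp(12)
        th = compute_thresholds(0.5, 0.5)  # m = 13
        assert segment_trace(s, th, 10.0) == []

    def test_isolated_reversal_does_not_break_run(self):
        # 14 rising increments with one interior dip: still one event
        s = np.cumsum(np.array([0.0] + [1.0] * 7 + [-0.5] + [1.0] * 7))
        s = np.concatenate([np.zeros(5), s + 0.0, np.full(5, s[-1])])
        th = compute_thresholds(0.5, 0.5)
        events = segment_trace(s, th, 1.0)
        assert len(events) == 1
        assert events[0].direction == POSITIVE

    def test_two_adjacent_interruptions_break_run(self):
        ups = [1.0] * 7
        s = np.cumsum(np.array([0.0] + ups + [-0.5, -0.5] + ups))
        th = compute_thresholds(0.5, 0.5)
        assert segment_trace(s, th, 1.0) == []  # neither half reaches 13

    def test_second_reversal_in_same_run_ends_it(self):
        # two separated dips inside what would otherwise be one long run:
        # only one may be bridged, so the run is cut at the second dip
        incs = [1.0] * 7 + [-0.5] + [1.0] * 7 + [-0.5] + [1.0] * 6
        s = np.cumsum([0.0] + incs)
        th = compute_thresholds(0.5, 0.5)
        events = segment_trace(s, th, 1.0)
        assert len(events) == 1
        assert events[0].direction == POSITIVE
        # run is the first 14 rising increments plus the bridged dip; the
        # second dip ends it, and the 6 trailing rises are sub-threshold
        assert events[0].end_index - events[0].start_index == 15

    def test_unclassified_gap_between_significant_events(self):
        up = _flat_with_ramp(15, height=100.0, n=60, start=10)
        down = -_flat_with_ramp(15, height=100.0, n=60, start=20)
        s = np.concatenate([up, up[-1] + down])
        th = compute_thresholds(0.5, 0.5)
        events = segment_trace(s, th, 10.0)
        directions = [e.direction for e in events]
        assert directions == [POSITIVE, UNCLASSIFIED, NEGATIVE]
        gap = events[1]
        assert gap.start_index == events[0].end_index
        assert gap.end_index == events[2].start_index

    def test_confinement_no_event_outside_first_last_significant(self):
        s = _flat_with_ramp(20, height=100.0, n=200, start=80)
        th = compute_thresholds(0.5, 0.5)
        events = segment_trace(s, th, 10.0)
        assert len(events) == 1  # flat spans before/after are discarded

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        arrays(
            float,
            st.integers(40, 200),
            elements=st.floats(-100, 100, allow_nan=False, width=32),
        )
    )
    def test_direction_symmetry_under_negation(self, s):
        # negating the trace swaps positive and negative events with the
        # same magnitudes, durations and indices
        th_fwd = compute_thresholds(0.5, 0.5)
        fwd = segment_trace(s, th_fwd, 10.0)
        rev = segment_trace(-s, th_fwd, 10.0)
        swap = {POSITIVE: NEGATIVE, NEGATIVE: POSITIVE, UNCLASSIFIED: UNCLASSIFIED}
        assert len(fwd) == len(rev)
        for a, b in zip(fwd, rev):
            assert swap[a.direction] == b.direction
            assert a.start_index == b.start_index and a.end_index == b.end_index
            assert a.amplitude == pytest.approx(-b.amplitude)
            assert a.duration_s == b.duration_s


class TestNullSpecificity:
    def test_run_probability_on_iid_increments_matches_closed_form(self):
        # P(10 consecutive positive increments at a fixed position) = 2^-10
        # for symmetric i.i.d. noise; Monte Carlo over >= 1e6 positions
        rng = np.random.default_rng(12345)
        m = 10
        n_pos = 1_200_000
        d = rng.normal(size=n_pos + m)
        up = (d > 0).astype(float)
        runs = np.convolve(up, np.ones(m), mode="valid")[:n_pos] == m
        p_hat = runs.mean()
        p_true = 0.5**m
        se = math.sqrt(p_true * (1 - p_true) / n_pos)
        assert p_true <= 1e-3
        assert abs(p_hat - p_true) < 3 * se


class TestInterEventIntervals:
    @staticmethod
    def _ev(direction, start):
        return BurstEvent(direction, start, start + 15, 50.0, 150.0)

    def test_start_to_start_intervals(self):
        events = [self._ev(POSITIVE, 0), self._ev(POSITIVE, 60), self._ev(POSITIVE, 120)]
        assert inter_event_intervals(events, POSITIVE, 10.0) == [600.0, 600.0]

    def test_single_event_gives_empty(self):
        assert inter_event_intervals([self._ev(POSITIVE, 0)], POSITIVE, 10.0) == []

    def test_directions_kept_separate(self):
        events = [self._ev(POSITIVE, 0), self._ev(NEGATIVE, 40), self._ev(POSITIVE, 80)]
        assert inter_event_intervals(events, POSITIVE, 10.0) == [800.0]
        assert inter_event_intervals(events, NEGATIVE, 10.0) == []

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            inter_event_intervals([], UNCLASSIFIED, 10.0)


class TestDetectBurstsEndToEnd:
    def test_noise_only_trace_keeps_thresholds_near_span(self):
        rng = np.random.default_rng(7)
        from granuletrace import smooth_trace

        s = smooth_trace(rng.normal(0.0, 1.0, 360), 13)
        events, th = detect_bursts(s, 10.0)
        assert th.m_inc == 13 and th.m_dec == 13  # p near 0.5 both ways
        assert 0.4 < th.p_inc < 0.6
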