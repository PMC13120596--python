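"""Event alignment, tolerance sensitivity, and duration-error statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import linear_sum_assignment

from desksense import (
    PostureState,
    TransitionEvent,
    UndefinedMetricError,
    ValidationConfig,
    align_events,
    bouts_from_events,
    duration_errors,
    find_delta_min,
    per_user_mae,
    sensitivity_at,
)
from desksense.validation import AlignmentResult, MatchedPair
from conftest import events

SIT, STAND = PostureState.SIT, PostureState.STAND


def greedy_oracle(sensor_ts, truth_ts):
    """Independent re-implementation of greedy |dt| matching.

    Exhaustively enumerates all (sensor, truth) pairs, repeatedly takes the
    smallest |dt| (ties: earlier truth, then earlier sensor), removing both
    members. Returns {(sensor_index, truth_index)}.
    """
    remaining = [
        (abs(s - g), g, s, si, gj)
        for si, s in enumerate(sensor_ts)
        for gj, g in enumerate(truth_ts)
    ]
    remaining.sort()
    chosen = set()
    used_s, used_g = set(), set()
    for _, _, _, si, gj in remaining:
        if si in used_s or gj in used_g:
            continue
        chosen.add((si, gj))
        used_s.add(si)
        used_g.add(gj)
    return chosen


def alternating_events(timestamps_ms):
    return [
        TransitionEvent(int(t), SIT if i % 2 == 0 else STAND)
        for i, t in enumerate(sorted(timestamps_ms))
    ]


class TestAlignEvents:
    def test_single_pair(self):
        al = align_events(alternating_events([10_000]), alternating_events([11_500]))
        assert len(al.pairs) == 1
        assert al.pairs[0].delta_s == pytest.approx(1.5)

    def test_surplus_truth_event_goes_missed(self):
        al = align_events(
            alternating_events([10_000, 100_000]),
            alternating_events([12_000, 60_000, 101_000]),
        )
        matched = {(p.sensor_index, p.truth_index) for p in al.pairs}
        assert matched == {(0, 0), (1, 2)}
        assert al.missed_truth == (1,)
        assert al.spurious_sensor == ()
        # on this instance greedy coincides with the optimal assignment
        cost = np.array([[2.0, 50.0, 91.0], [88.0, 40.0, 1.0]])
        rows, cols = linear_sum_assignment(cost)
        assert matched == set(zip(rows.tolist(), cols.tolist()))

    def test_empty_sensor_log_all_missed(self):
        al = align_events([], alternating_events([1000, 2000]))
        assert al.pairs == ()
        assert al.missed_truth == (0, 1)

    def test_greedy_is_not_minimum_cost_assignment(self):
        # documented divergence: greedy grabs (5 s, 4 s) and is forced into
        # (0 s, 6 s), total 7 s; the optimal assignment costs 5 s
        al = align_events(
            alternating_events([0, 5000]), alternating_events([4000, 6000])
        )
        assert {(p.sensor_index, p.truth_index) for p in al.pairs} == {
            (1, 0),
            (0, 1),
        }
        assert sum(p.delta_s for p in al.pairs) == pytest.approx(7.0)

    @given(
        sensor=st.lists(st.integers(0, 500), max_size=8, unique=True),
        truth=st.lists(st.integers(0, 500), max_size=8, unique=True),
    )
    def test_matches_exhaustive_greedy_oracle(self, sensor, truth):
        sensor, truth = sorted(sensor), sorted(truth)
        al = align_events(
            alternating_events([t * 1000 for t in sensor]),
            alternating_events([t * 1000 for t in truth]),
        )
        got = {(p.sensor_index, p.truth_index) for p in al.pairs}
        assert got == greedy_oracle(sensor, truth)
        # full matching: min(|S|, |G|) pairs, no double use
        assert len(got) == min(len(sensor), len(truth))
        assert len({s for s, _ in got}) == len(got)
        assert len({g for _, g in got}) == len(got)


def make_alignment(pair_deltas_s, n_truth):
    """Alignment stub with given pair deltas and ground-truth count."""
    truth = alternating_events([i * 100_000 for i in range(n_truth)])
    sensor = [
        TransitionEvent(truth[i].timestamp_ms + int(d * 1000), truth[i].new_state)
        for i, d in enumerate(pair_deltas_s)
    ]
    pairs = tuple(
        MatchedPair(i, i, sensor[i], truth[i], float(d))
        for i, d in enumerate(pair_deltas_s)
    )
    return AlignmentResult(
        sensor_events=tuple(sensor),
        truth_events=tuple(truth),
        pairs=pairs,
        missed_truth=tuple(range(len(pair_deltas_s), n_truth)),
        spurious_sensor=(),
    )


class TestSensitivity:
    def test_direct_count(self):
        al = make_alignment([1, 2, 6], 4)
        assert sensitivity_at(al, 3) == pytest.approx(50.0)
        assert sensitivity_at(al, 10) == pytest.approx(75.0)

    def test_all_exact_pairs_any_delta(self):
        al = make_alignment([0, 0, 0], 3)
        assert sensitivity_at(al, 0.5) == 100.0

    def test_no_truth_events_undefined(self):
        al = align_events([], [])
        with pytest.raises(UndefinedMetricError):
            sensitivity_at(al, 5)

    @given(
        deltas=st.lists(st.floats(0, 20), min_size=1, max_size=30),
        d1=st.floats(0, 12),
        d2=st.floats(0, 12),
    )
    def test_monotone_in_delta(self, deltas, d1, d2):
        al = make_alignment(deltas, len(deltas) + 2)
        lo, hi = sorted((d1, d2))
        assert sensitivity_at(al, lo) <= sensitivity_at(al, hi)


class TestDeltaMin:
    def test_first_plateau_onset(self):
        # phi = 40,70,81,81,... -> plateau under the 5-s cap starts at 3 s
        deltas = [0.5] * 4 + [1.5] * 3 + [2.5] + [10.5] * 2
        al = make_alignment(deltas, 10)
        curve = find_delta_min(al)
        assert curve.values[:5] == (40.0, 70.0, 80.0, 80.0, 80.0)
        assert curve.delta_min == 3
        assert curve.plateau_found

    def test_perfect_curve_picks_smallest_grid_delta(self):
        al = make_alignment([0.2] * 5, 5)
        assert find_delta_min(al).delta_min == 1

    def test_rising_curve_falls_back_to_cap_with_warning(self):
        # one pair per grid step: strictly increasing through 10 s
        al = make_alignment([d - 0.5 for d in range(1, 11)], 10)
        curve = find_delta_min(al)
        assert curve.delta_min == 5  # the cap
        assert not curve.plateau_found

    def test_delta_min_is_in_grid_and_capped(self):
        al = make_alignment([1.2, 2.2, 2.4], 3)
        cfg = ValidationConfig(max_tolerance_s=5.0)
        curve = find_delta_min(al, cfg)
        assert curve.delta_min in cfg.delta_grid_s
        assert curve.delta_min <= cfg.max_tolerance_s


class TestDurationErrors:
    @staticmethod
    def logs_to_inputs(sensor_ev, truth_ev, end_ms):
        al = align_events(sensor_ev, truth_ev)
        return (
            bouts_from_events(sensor_ev, end_ms),
            bouts_from_events(truth_ev, end_ms),
            al,
        )

    def test_mae_is_mean_absolute_duration_difference(self):
        truth = events((0, "sit"), (60_000, "stand"), (120_000, "sit"))
        sensor = events((0, "sit"), (61_000, "stand"), (119_000, "sit"))
        s_bouts, t_bouts, al = self.logs_to_inputs(sensor, truth, 180_000)
        # paired duration diffs: |61-60|=1, |58-60|=2, |61-60|=1
        summary = duration_errors(s_bouts, t_bouts, al, 5.0)
        assert summary.mae_s == pytest.approx(4.0 / 3.0)
        assert summary.count_bias == 0

    def test_identical_logs_zero_error(self):
        truth = events((0, "sit"), (60_000, "stand"))
        s_bouts, t_bouts, al = self.logs_to_inputs(truth, truth, 120_000)
        summary = duration_errors(s_bouts, t_bouts, al, 5.0)
        assert summary.mae_s == 0.0
        assert summary.count_bias == 0
        assert summary.ci95_lower_min == summary.ci95_upper_min == 0.0

    def test_count_bias_sign_convention(self):
        # sensor misses one truth event: N_sensor - N_truth = -1
        truth = events((0, "sit"), (60_000, "stand"), (120_000, "sit"))
        sensor = events((0, "sit"), (60_500, "stand"))
        s_bouts, t_bouts, al = self.logs_to_inputs(sensor, truth, 180_000)
        summary = duration_errors(s_bouts, t_bouts, al, 5.0)
        assert summary.count_bias == -1

    def test_missed_event_inflates_preceding_sensor_bout(self):
        # deleting one event from a log lengthens the preceding bout by
        # exactly the missed bout's duration
        truth = events(
            (0, "sit"), (60_000, "stand"), (150_000, "sit"), (240_000, "stand")
        )
        sensor = [truth[0], truth[1], truth[3]]  # event at 150 s missed
        t_bouts = bouts_from_events(truth, 300_000)
        s_bouts = bouts_from_events(sensor, 300_000)
        # truth stand bout 60-150 s is 90 s; sensor's is 60-240 s = 180 s
        assert s_bouts[1].duration_s - t_bouts[1].duration_s == pytest.approx(
            t_bouts[2].duration_s
        )

    def test_every_pair_used_respects_delta_min(self):
        truth = events((0, "sit"), (60_000, "stand"), (120_000, "sit"))
        sensor = events((0, "sit"), (67_000, "stand"), (121_000, "sit"))
        s_bouts, t_bouts, al = self.logs_to_inputs(sensor, truth, 180_000)
        summary = duration_errors(s_bouts, t_bouts, al, 2.0)
        # the 7-s-late event is excluded by the tolerance
        assert summary.n == 2

    def test_no_matches_undefined(self):
        truth = events((0, "sit"))
        sensor = events((90_000, "sit"))
        s_bouts, t_bouts, al = self.logs_to_inputs(sensor, truth, 200_000)
        with pytest.raises(UndefinedMetricError):
            duration_errors(s_bouts, t_bouts, al, 1.0)


class TestPerUserMae:
    def test_single_user_equals_pooled(self):
        truth = events((0, "sit"), (60_000, "stand"), (120_000, "sit"))
        sensor = events((0, "sit"), (61_000, "stand"), (119_000, "sit"))
        al = align_events(sensor, truth)
        s_bouts = bouts_from_events(sensor, 180_000)
        t_bouts = bouts_from_events(truth, 180_000)
        pooled = duration_errors(s_bouts, t_bouts, al, 5.0)
        (per,) = per_user_mae({"U1": (s_bouts, t_bouts, al)}, 5.0)
        assert per.mae_s == pytest.approx(pooled.mae_s)
        assert per.n == pooled.n

    def test_event_weighted_mean_recovers_pooled_mae(self):
        # user A: one diff of 0 s (2 events); user B: diffs of 2 s
        truth_a = events((0, "sit"), (60_000, "stand"))
        per_a = (
            bouts_from_events(truth_a, 120_000),
            bouts_from_events(truth_a, 120_000),
            align_events(truth_a, truth_a),
        )
        truth_b = events((0, "sit"), (60_000, "stand"))
        sensor_b = events((0, "sit"), (62_000, "stand"))
        per_b = (
            bouts_from_events(sensor_b, 120_000),
            bouts_from_events(truth_b, 120_000),
            align_events(sensor_b, truth_b),
        )
        result = per_user_mae({"A": per_a, "B": per_b}, 5.0)
        maes = {r.user_id: r.mae_s for r in result}
        ns = {r.user_id: r.n for r in result}
        assert maes["A"] == pytest.approx(0.0)
        assert maes["B"] == pytest.approx(2.0)
        pooled = sum(maes[u] * ns[u] for u in maes) / sum(ns.values())
        assert pooled == pytest.approx(1.0)
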