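"""Trial segmentation, engagement labels, speed split, lick metrics."""

import numpy as np
import pytest

from conftest import constant_speed_trace
from prospectcode import behavior as beh
from prospectcode.geometry import FOLDED_BINS
from prospectcode.session import BehaviorTrace


# --- smoothing


def test_smooth_constant_trace_unchanged(geometry):
    tr = constant_speed_trace(1.0)
    out = beh.smooth_trace(tr, 25)
    assert np.allclose(out.speed, tr.speed)


def test_smooth_window_one_is_identity():
    tr = constant_speed_trace(1.0)
    out = beh.smooth_trace(tr, 1)
    assert out is tr


def test_smooth_step_matches_convolution_oracle():
    t = np.arange(0, 10, 0.02)
    speed = np.where(t < 5, 10.0, 30.0)
    tr = BehaviorTrace(
        time=t, position=np.mod(10 * t, 360), speed=speed, licks=[], rewards=[]
    )
    w = 11
    out = beh.smooth_trace(tr, w)
    kernel = np.ones(w) / w
    expected = np.convolve(speed, kernel, mode="same") / np.convolve(
        np.ones_like(speed), kernel, mode="same"
    )
    assert np.allclose(out.speed, expected)


def test_smooth_position_wraps_on_circle():
    # positions straddling the 0/360 wrap must not smear across the circle
    t = np.arange(0, 2, 0.02)
    pos = np.mod(355.0 + 10.0 * t, 360.0)
    tr = BehaviorTrace(time=t, position=pos, speed=np.full_like(t, 10.0), licks=[], rewards=[])
    out = beh.smooth_trace(tr, 9)
    jumps = np.abs(np.diff(out.position))
    assert np.sum((jumps > 1.0) & (jumps < 350.0)) == 0


def test_smooth_window_errors():
    tr = constant_speed_trace(0.2)
    with pytest.raises(ValueError):
        beh.smooth_trace(tr, 0)
    with pytest.raises(ValueError):
        beh.smooth_trace(tr, len(tr.time) + 1)


# --- segmentation


def test_three_laps_give_six_half_lap_trials(geometry):
    tr = constant_speed_trace(3.0)
    trials = beh.segment_trials(tr, geometry)
    assert len(trials) == 6
    # consecutive and non-overlapping
    for a, b in zip(trials[:-1], trials[1:]):
        assert a.end_idx == b.start_idx
    # alternating reward zones
    zones = [t.reward_zone for t in trials]
    assert zones[0::2] != zones[1::2]


def test_partial_final_lap_excluded(geometry):
    tr = constant_speed_trace(2.6)
    trials = beh.segment_trials(tr, geometry)
    assert len(trials) == 5


def test_never_completing_half_lap_returns_empty(geometry):
    tr = constant_speed_trace(0.3)
    assert beh.segment_trials(tr, geometry) == []


def test_generator_trials_match_ground_truth(default_session, default_trials):
    bounds = default_session.ground_truth["lap_boundary_times"]
    # each lap contains two half-lap trials; compare trial starts falling
    # on lap boundaries (every second trial boundary is a lap boundary)
    starts = [t.start_s for t in default_trials]
    for b in bounds[1:-1]:
        assert min(abs(s - b) for s in starts) < 0.5


# --- classification


def test_classification_rules(geometry):
    rz_lo, rz_hi = geometry.reward_zone_spans[0]
    tr = constant_speed_trace(1.0, speed=36.0)  # 10 s for 360 deg
    trials = beh.segment_trials(tr, geometry)

    def lick_time_at(pos_deg):
        # invert position for the constant-speed trace
        origin = geometry.reward_zone_ends[0]
        return float(np.mod(pos_deg - origin, 360.0) / 36.0)

    in_rz = lick_time_at((rz_lo + rz_hi) / 2 + 180.0)  # second trial's zone
    # trial containing that time
    tr_licked = BehaviorTrace(
        time=tr.time, position=tr.position, speed=tr.speed,
        licks=[in_rz], rewards=[in_rz],
    )
    labels = [beh.classify_trial(t, tr_licked, geometry) for t in trials]
    assert "correct" in labels
    assert all(lbl in ("correct", "unengaged") for lbl in labels)

    # licks only outside the reward zone -> "other"
    out_rz = lick_time_at(np.mod(rz_lo - 40.0, 360.0))
    tr_out = BehaviorTrace(
        time=tr.time, position=tr.position, speed=tr.speed, licks=[out_rz], rewards=[]
    )
    labels = [beh.classify_trial(t, tr_out, geometry) for t in trials]
    assert "other" in labels

    # no licks at all -> unengaged
    labels = [beh.classify_trial(t, tr, geometry) for t in trials]
    assert set(labels) == {"unengaged"}


def test_generator_engagement_recovered_exactly(default_session, default_trials):
    engaged = default_session.ground_truth["lap_engaged"]
    # trials alternate within laps; both half-laps share the lap's engagement
    bounds = default_session.ground_truth["lap_boundary_times"]
    for t in default_trials:
        lap = int(np.searchsorted(bounds, t.start_s + 1e-6) - 1)
        expected = "correct" if engaged[lap] else "unengaged"
        assert t.label == expected


# --- speed split


def _trial(i, speed, label="correct"):
    t = beh.Trial(
        trial_id=i, start_idx=0, end_idx=1, start_s=0, end_s=1, reward_zone=4, label=label
    )
    t.mean_speed_outside_reward = speed
    return t


def test_median_split_example():
    trials = [_trial(i, s) for i, s in enumerate([1.0, 2.0, 3.0, 4.0])]
    beh.split_fast_slow(trials)
    assert [t.speed_class for t in trials] == ["slow", "slow", "fast", "fast"]


def test_all_equal_speeds_are_slow():
    trials = [_trial(i, 2.0) for i in range(4)]
    beh.split_fast_slow(trials)
    assert all(t.speed_class == "slow" for t in trials)


def test_split_invariant_to_order_and_pooled_median():
    speeds = [5.0, 1.0, 4.0, 2.0, 3.0, 6.0]
    trials = [_trial(i, s) for i, s in enumerate(speeds)]
    beh.split_fast_slow(trials)
    by_id = {t.trial_id: t.speed_class for t in trials}
    # brute-force oracle
    med = float(np.median(speeds))
    for i, s in enumerate(speeds):
        assert by_id[i] == ("fast" if s > med else "slow")
    # shuffled order gives identical classes
    rng = np.random.default_rng(0)
    shuffled = [trials[k] for k in rng.permutation(len(trials))]
    for t in shuffled:
        t.speed_class = "unset"
    beh.split_fast_slow(shuffled)
    assert {t.trial_id: t.speed_class for t in shuffled} == by_id


def test_split_requires_two_correct_trials():
    with pytest.raises(ValueError):
        beh.split_fast_slow([_trial(0, 1.0)])


# --- lick fraction


def test_lick_fraction_cases(geometry):
    tr = constant_speed_trace(1.0, speed=36.0)
    trials = beh.segment_trials(tr, geometry)
    trial = trials[0]

    # no licks -> zero vector
    vec = beh.lick_fraction_by_position(trial, tr, geometry)
    assert np.all(vec == 0)

    # all licks at one time -> indicator
    t_mid = (trial.start_s + trial.end_s) / 2
    tr2 = BehaviorTrace(
        time=tr.time, position=tr.position, speed=tr.speed,
        licks=[t_mid, t_mid + 1e-3], rewards=[],
    )
    vec = beh.lick_fraction_by_position(trial, tr2, geometry)
    assert vec.sum() == pytest.approx(1.0)
    assert (vec > 0).sum() == 1

    # 2 licks in one bin, 2 in another -> 0.5 / 0.5
    t_a, t_b = trial.start_s + 0.5, trial.start_s + 3.0
    tr3 = BehaviorTrace(
        time=tr.time, position=tr.position, speed=tr.speed,
        licks=[t_a, t_a + 1e-3, t_b, t_b + 1e-3], rewards=[],
    )
    vec = beh.lick_fraction_by_position(trial, tr3, geometry)
    assert sorted(vec[vec > 0]) == [0.5, 0.5]
    assert len(vec) == FOLDED_BINS.n_bins
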