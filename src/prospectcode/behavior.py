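"""Trial segmentation, engagement classification and behavioral metrics.

A trial is one half-lap: from the exit of one reward zone through the end
of the next reward zone (the two reward zones sit 180 degrees apart, so
half-laps tile the session). Trials where the animal licked in the reward
zone (and was rewarded) are "correct"; trials with no licks anywhere are
"unengaged"; trials with licks only outside the reward zone get the label
"other" and are excluded from both groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import FOLDED_TRACK_DEG, BinGeometry, FOLDED_BINS, TrackGeometry
from .session import BehaviorTrace


@dataclass
class Trial:
    trial_id: int
    start_idx: int
    end_idx: int           # exclusive
    start_s: float
    end_s: float
    reward_zone: int       # which of the two reward zones ends the trial
    label: str = "other"
    mean_speed_outside_reward: float = np.nan
    speed_class: str = "unset"
    anticipatory_lick_fraction: float = np.nan

    def contains(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.start_s) & (t < self.end_s)


def smooth_trace(trace: BehaviorTrace, window: int) -> BehaviorTrace:
    """Moving-average smoothing; position is smoothed on the circle."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(trace.time):
        raise ValueError("window longer than trace")
    if window == 1:
        return trace
    kernel = np.ones(window) / window
    unwrapped = np.unwrap(np.deg2rad(trace.position))
    pos = np.mod(np.rad2deg(_smooth_same(unwrapped, kernel)), 360.0)
    speed = _smooth_same(trace.speed, kernel)
    return BehaviorTrace(
        time=trace.time, position=pos, speed=speed, licks=trace.licks, rewards=trace.rewards
    )


def _smooth_same(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """'same'-mode moving average with edge renormalization."""
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def segment_trials(trace: BehaviorTrace, geometry: TrackGeometry) -> list[Trial]:
    """Split the trace into consecutive half-lap trials.

    Boundaries are forward crossings of a reward-zone end. Partial
    traversals before the first or after the last boundary are dropped.
    """
    origin = geometry.reward_zone_ends[0]
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(trace.position))) - origin
    # distance axis whose integer multiples of 180 are reward-zone exits
    u = np.maximum.accumulate(unwrapped)
    k0 = int(np.ceil(u[0] / FOLDED_TRACK_DEG - 1e-9))
    k1 = int(np.floor(u[-1] / FOLDED_TRACK_DEG + 1e-9))
    levels = np.arange(k0, k1 + 1) * FOLDED_TRACK_DEG
    boundaries = np.searchsorted(u, levels - 1e-9, side="left")
    trials = []
    for k in range(len(boundaries) - 1):
        a, b = int(boundaries[k]), int(boundaries[k + 1])
        # the half-lap ending at level m terminates in alternating reward zones
        zone = (k0 + k + 1) % 2
        trials.append(
            Trial(
                trial_id=k,
                start_idx=a,
                end_idx=b,
                start_s=float(trace.time[a]),
                end_s=float(trace.time[b]) if b < len(trace.time) else float(trace.time[-1]),
                reward_zone=geometry.reward_zone_indices[zone],
            )
        )
    return trials


def classify_trial(trial: Trial, trace: BehaviorTrace, geometry: TrackGeometry) -> str:
    """correct: licked in the reward zone; unengaged: no licks at all."""
    in_trial = trial.contains(trace.licks)
    licks = trace.licks[in_trial]
    if len(licks) == 0:
        return "unengaged"
    lick_pos = trace.position_at(licks)
    if np.any(geometry.in_reward_zone(lick_pos)):
        return "correct"
    return "other"


def classify_trials(trials: list[Trial], trace: BehaviorTrace, geometry: TrackGeometry) -> list[Trial]:
    for tr in trials:
        tr.label = classify_trial(tr, trace, geometry)
        tr.mean_speed_outside_reward = mean_speed_outside_reward(tr, trace, geometry)
        tr.anticipatory_lick_fraction = anticipatory_lick_fraction(tr, trace, geometry)
    return trials


def mean_speed_outside_reward(trial: Trial, trace: BehaviorTrace, geometry: TrackGeometry) -> float:
    """Mean speed outside the last half of the anticipatory zone and the reward zone."""
    sl = slice(trial.start_idx, trial.end_idx)
    folded = geometry.fold(trace.position[sl])
    # excluded region: last half anticipatory zone + reward zone = folded [153, 180)
    cutoff = FOLDED_TRACK_DEG - 1.5 * geometry.zone_width_deg
    mask = folded < cutoff
    if not mask.any():
        return np.nan
    return float(trace.speed[sl][mask].mean())


def anticipatory_lick_fraction(trial: Trial, trace: BehaviorTrace, geometry: TrackGeometry) -> float:
    licks = trace.licks[trial.contains(trace.licks)]
    if len(licks) == 0:
        return 0.0
    pos = trace.position_at(licks)
    return float(np.mean(geometry.in_anticipatory_zone(pos)))


def split_fast_slow(trials: list[Trial]) -> list[Trial]:
    """Median split of correct trials by speed outside rewarded areas.

    The median is pooled over all supplied correct trials; trials strictly
    above the median are fast, the rest (including exact ties) slow.
    """
    correct = [t for t in trials if t.label == "correct"]
    if len(correct) < 2:
        raise ValueError("need at least 2 correct trials for a median split")
    speeds = np.array([t.mean_speed_outside_reward for t in correct])
    median = float(np.median(speeds))
    for t in correct:
        t.speed_class = "fast" if t.mean_speed_outside_reward > median else "slow"
    return trials


def lick_fraction_by_position(
    trial: Trial,
    trace: BehaviorTrace,
    geometry: TrackGeometry,
    bins: BinGeometry = FOLDED_BINS,
) -> np.ndarray:
    """Fraction of the trial's licks in each folded position bin.

    Sums to 1 when the trial has licks, all zeros otherwise.
    """
    licks = trace.licks[trial.contains(trace.licks)]
    counts = np.zeros(bins.n_bins)
    if len(licks) == 0:
        return counts
    folded = geometry.fold(trace.position_at(licks))
    np.add.at(counts, bins.bin_index(folded), 1.0)
    return counts / counts.sum()


def trial_table(trials: list[Trial]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "start_s": [t.start_s for t in trials],
            "end_s": [t.end_s for t in trials],
            "reward_zone": [t.reward_zone for t in trials],
            "label": [t.label for t in trials],
            "speed_class": [t.speed_class for t in trials],
            "mean_speed_deg_s": [t.mean_speed_outside_reward for t in trials],
            "anticipatory_lick_fraction": [t.anticipatory_lick_fraction for t in trials],
        }
    )
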