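"""Theta-cycle decoding: quadrant ratio, shuffle test, prospective coding.

Theta troughs are identified from the Hilbert phase of the 4-12 Hz LFP
during running on correct trials. A 400 ms window centered on each trough
is decoded in 20 ms bins (bins with >= 2 spikes) and the posterior is
re-centered on the animal's position at the trough. Averaged over cycles,
sequence strength is the quadrant ratio over the +/-80 ms x +/-45 degree
box

    quadrant ratio = (Q1 + Q3 - (Q2 + Q4)) / (Q1 + Q2 + Q3 + Q4)

with Q1 the future (0..80 ms, 0..45 deg) and Q3 the past (-80..0 ms,
-45..0 deg) quadrant, tested against 500 within-cycle time-bin shuffles.
Prospective coding is scored as (Q1 - Q3) / (Q1 + Q3): +1 when the
sequence carries only upcoming positions, -1 when only past ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import Trial
from .config import THETA_BAND, PipelineConfig
from .decoding import decode_windows
from .geometry import BinGeometry, TrackGeometry
from .lfp import bandpass, hilbert_phase
from .session import BehaviorTrace, StateIntervals


@dataclass
class ThetaCycleDecoding:
    trough_s: float
    posterior: np.ndarray       # (n_time_bins, n_rel_bins), NaN rows undecoded
    rel_centers: np.ndarray     # degrees relative to the animal, bin centers
    time_centers: np.ndarray    # seconds relative to the trough
    animal_position: float      # folded (or absolute) position at the trough
    trial_id: int = -1
    speed_class: str = "unset"

    @property
    def decoded(self) -> np.ndarray:
        return ~np.isnan(self.posterior).any(axis=1)


@dataclass
class CodingStats:
    q1: float
    q2: float
    q3: float
    q4: float
    quadrant_ratio: float
    prospective_ratio: float
    prospective_defined: bool
    n_cycles: int
    shuffle_p95: float = np.nan
    significant: bool = False


def extract_theta_cycles(
    lfp: np.ndarray,
    rate: float,
    behavior: BehaviorTrace,
    states: StateIntervals | None = None,
    trials: list[Trial] | None = None,
    cfg: PipelineConfig | None = None,
) -> np.ndarray:
    """Theta trough times during running (on correct trials when given).

    Troughs are +pi -> -pi wraps of the 4-12 Hz Hilbert phase, i.e. minima
    of the theta oscillation.
    """
    cfg = cfg or PipelineConfig()
    phase = hilbert_phase(bandpass(np.asarray(lfp, dtype=float), THETA_BAND, rate))
    wraps = np.flatnonzero(np.diff(phase) < -np.pi) + 1
    troughs = wraps / rate
    keep = behavior.speed_at(troughs) > cfg.movement_speed_min
    if states is not None and states.theta_periods:
        keep &= states.in_theta(troughs)
    elif states is not None:
        keep &= False
    if trials is not None:
        correct = np.zeros(len(troughs), dtype=bool)
        for tr in trials:
            if tr.label == "correct":
                correct |= tr.contains(troughs)
        keep &= correct
    return troughs[keep]


def recenter_posterior(
    posterior: np.ndarray, bins: BinGeometry, animal_position: float
) -> tuple[np.ndarray, np.ndarray]:
    """Roll position bins so the animal's bin sits at the center column.

    Returns the rolled posterior and the relative-position bin centers,
    (j - n/2) * bin_width degrees.
    """
    n = bins.n_bins
    center = n // 2
    ia = bins.bin_index(np.array([animal_position]))[0]
    rolled = np.roll(posterior, center - ia, axis=-1)
    rel = (np.arange(n) - center) * bins.bin_width_deg
    return rolled, rel


def decode_theta_cycle(
    trough_s: float,
    spike_times_by_unit: list[np.ndarray],
    rates: np.ndarray,
    bins: BinGeometry,
    animal_position: float,
    cfg: PipelineConfig | None = None,
) -> ThetaCycleDecoding | None:
    """Decode one 400 ms theta window and re-center it on the animal.

    ``animal_position`` must be expressed on the same (folded or full)
    axis as the rate maps. Returns None when no bin reaches the spike
    minimum.
    """
    cfg = cfg or PipelineConfig()
    half = cfg.theta_window_s / 2
    edges = trough_s + np.arange(-half, half + cfg.theta_bin_s / 2, cfg.theta_bin_s)
    dec = decode_windows(
        spike_times_by_unit, rates, edges, cfg.theta_bin_s, bins,
        min_spikes=cfg.decode_min_spikes, cfg=cfg,
    )
    if not dec.decoded.any():
        return None
    post, rel = recenter_posterior(dec.posterior, bins, animal_position)
    t_centers = 0.5 * (edges[:-1] + edges[1:]) - trough_s
    return ThetaCycleDecoding(
        trough_s=trough_s,
        posterior=post,
        rel_centers=rel,
        time_centers=t_centers,
        animal_position=animal_position,
    )


def _quadrant_masks(
    time_centers: np.ndarray, rel_centers: np.ndarray, cfg: PipelineConfig
) -> dict[str, np.ndarray]:
    t = time_centers[:, None]
    x = rel_centers[None, :]
    tmax = cfg.quadrant_time_ms / 1000.0
    xmax = cfg.quadrant_pos_deg
    tin = (np.abs(t) <= tmax + 1e-12) & (np.abs(t) > 1e-12)
    xin = (np.abs(x) <= xmax + 1e-9) & (np.abs(x) > 1e-9)
    box = tin & xin
    return {
        "q1": box & (t > 0) & (x > 0),
        "q2": box & (t < 0) & (x > 0),
        "q3": box & (t < 0) & (x < 0),
        "q4": box & (t > 0) & (x < 0),
    }


def average_cycles(decodings: list[ThetaCycleDecoding]) -> np.ndarray:
    """Element-wise mean posterior; undecoded time bins excluded per cycle."""
    if not decodings:
        raise ValueError("no decoded cycles to average")
    stack = np.stack([d.posterior for d in decodings])
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(stack, axis=0)


def score_average(
    avg: np.ndarray,
    time_centers: np.ndarray,
    rel_centers: np.ndarray,
    cfg: PipelineConfig | None = None,
    n_cycles: int = 0,
) -> CodingStats:
    """Quadrant sums and both ratios for one averaged cycle matrix."""
    cfg = cfg or PipelineConfig()
    masks = _quadrant_masks(time_centers, rel_centers, cfg)
    sums = {}
    for name, mask in masks.items():
        vals = avg[mask]
        sums[name] = float(np.nansum(vals))
    q1, q2, q3, q4 = sums["q1"], sums["q2"], sums["q3"], sums["q4"]
    total = q1 + q2 + q3 + q4
    quadrant_ratio = (q1 + q3 - (q2 + q4)) / total if total > 0 else np.nan
    defined = (q1 + q3) > 0
    prospective = (q1 - q3) / (q1 + q3) if defined else np.nan
    return CodingStats(
        q1=q1, q2=q2, q3=q3, q4=q4,
        quadrant_ratio=quadrant_ratio,
        prospective_ratio=prospective,
        prospective_defined=bool(defined),
        n_cycles=n_cycles,
    )


def average_and_score(
    decodings: list[ThetaCycleDecoding], cfg: PipelineConfig | None = None
) -> CodingStats:
    cfg = cfg or PipelineConfig()
    avg = average_cycles(decodings)
    d0 = decodings[0]
    return score_average(avg, d0.time_centers, d0.rel_centers, cfg, n_cycles=len(decodings))


def sequence_significance(
    decodings: list[ThetaCycleDecoding],
    cfg: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[bool, float, np.ndarray]:
    """Shuffle test of the session-average quadrant ratio.

    Each of 500 shuffles permutes the time-bin order independently within
    every decoded cycle, re-averages and recomputes the quadrant ratio;
    the session is significant when the observed ratio exceeds the 95th
    percentile of the null.
    """
    cfg = cfg or PipelineConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    observed = average_and_score(decodings, cfg).quadrant_ratio
    d0 = decodings[0]
    n_t = len(d0.time_centers)
    stack = np.stack([d.posterior for d in decodings])
    null = np.empty(cfg.sequence_shuffles)
    for s in range(cfg.sequence_shuffles):
        shuffled = np.empty_like(stack)
        for c in range(stack.shape[0]):
            shuffled[c] = stack[c, rng.permutation(n_t)]
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore", category=RuntimeWarning)
            avg = np.nanmean(shuffled, axis=0)
        null[s] = score_average(
            avg, d0.time_centers, d0.rel_centers, cfg, n_cycles=len(decodings)
        ).quadrant_ratio
    p95 = float(np.nanpercentile(null, 95))
    return bool(observed > p95), float(observed), null


def prospective_by_position_and_speed(
    decodings: list[ThetaCycleDecoding],
    trials: list[Trial],
    track: TrackGeometry,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Prospective coding ratio per (folded position zone, speed class).

    Each cycle inherits the speed class of its trial; ratios come from the
    averaged posterior of each group. Aggregate rows cover the
    reward-related (anticipatory + reward) zones and the post-reward zones.
    Empty groups are simply absent.
    """
    cfg = cfg or PipelineConfig()
    speed_of_trial = {t.trial_id: t.speed_class for t in trials}
    for d in decodings:
        d.speed_class = speed_of_trial.get(d.trial_id, "unset")

    zone_w = track.zone_width_deg
    n_zones = int(180.0 / zone_w)
    rows = []

    def _score(group, zone_label, speed_label):
        if not group:
            return
        stats = average_and_score(group, cfg)
        rows.append(
            {
                "zone": zone_label,
                "speed_class": speed_label,
                "n_cycles": len(group),
                "prospective_ratio": stats.prospective_ratio,
                "quadrant_ratio": stats.quadrant_ratio,
            }
        )

    for speed in ("all", "fast", "slow"):
        sel = [
            d for d in decodings if speed == "all" or d.speed_class == speed
        ]
        for z in range(n_zones):
            grp = [d for d in sel if int(d.animal_position // zone_w) == z]
            _score(grp, f"zone_{z}", speed)
        reward_rel = [
            d for d in sel if d.animal_position >= 180.0 - 2 * zone_w
        ]
        _score(reward_rel, "reward_related", speed)
        post_reward = [
            d for d in sel
            if d.animal_position < cfg.post_reward_n_zones * zone_w
        ]
        _score(post_reward, "post_reward", speed)
    return pd.DataFrame(rows)


def unoccupied_zone_flag(
    avg: np.ndarray,
    rel_centers: np.ndarray,
    cfg: PipelineConfig | None = None,
) -> tuple[bool, bool]:
    """Far-zone (162-198 deg away) decoding flag for one averaged matrix.

    Returns (flagged, degenerate). The far-zone mass is the mean posterior
    over relative positions at circular distance >= 162 degrees; the
    threshold is mean + 2 SD over all decoded elements. A zero-SD
    (uniform) average is degenerate and never flagged.
    """
    cfg = cfg or PipelineConfig()
    lo = cfg.far_zone_span_deg[0]
    mask = np.abs(rel_centers) >= lo
    vals = avg[~np.isnan(avg)]
    if vals.size == 0 or not mask.any():
        return False, True
    mean, sd = float(vals.mean()), float(vals.std())
    far = avg[:, mask]
    far = far[~np.isnan(far)]
    if far.size == 0:
        return False, True
    if sd == 0:
        return False, True
    return bool(far.mean() >= mean + 2 * sd), False


def unoccupied_zone_theta(
    decodings_fulltrack: list[ThetaCycleDecoding],
    trials: list[Trial],
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-trial unoccupied far-zone decoding flags (full-track cycles)."""
    cfg = cfg or PipelineConfig()
    rows = []
    by_trial: dict[int, list[ThetaCycleDecoding]] = {}
    for d in decodings_fulltrack:
        by_trial.setdefault(d.trial_id, []).append(d)
    for trial_id, group in sorted(by_trial.items()):
        avg = average_cycles(group)
        flagged, degenerate = unoccupied_zone_flag(avg, group[0].rel_centers, cfg)
        rows.append(
            {
                "trial_id": trial_id,
                "n_cycles": len(group),
                "far_zone_flag": flagged,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
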