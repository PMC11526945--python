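"""Synthetic annular-track sessions with known ground truth.

The generator emulates the study's task: head-fixed runs around a 360
degree annular track with 20 cue zones and two reward zones 180 degrees
apart, pausing and licking at rewards. It produces

* behavior (50 Hz position/speed, lick and reward events),
* multi-channel LFP (2 kHz) with theta-dominated running epochs,
  delta-dominated pauses, an embedded slow-gamma oscillation and
  ripple-band bursts at known times with a per-channel amplitude gradient,
* spikes from place cells tiling the track (von Mises tuning, theta-phase
  sweep with a controllable forward/backward bias), interneurons, uniform
  background spikes, von Mises spike-gamma coupling of controllable
  concentration, and ordered replay spikes inside each ripple whose
  forward probability is controllable.

Every stochastic choice flows from one seeded generator, so identical
configs are byte-identical. The generator is a testing instrument: its
parameters are ground truth the analysis pipeline must recover, not a
model of hippocampal biophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import FOLDED_TRACK_DEG, TrackGeometry, circ_diff, wrap_angle
from .session import BehaviorTrace, LfpChannelSet, Session, SpikeUnit

BEHAVIOR_RATE = 50.0     # Hz
SPIKE_GRID_RATE = 500.0  # Hz grid for inhomogeneous-Poisson thinning
GAMMA_FREQ = 32.0        # Hz, embedded slow-gamma used for coupling
RIPPLE_FREQ = 180.0      # Hz carrier of injected SWR bursts


@dataclass
class SyntheticConfig:
    duration_s: float = 900.0
    lfp_rate: float = 2000.0
    n_place_cells: int = 40
    n_nonspatial_cells: int = 5      # uniform-firing pyramidal cells
    n_interneurons: int = 5
    track_zones: int = 20
    reward_zone_indices: tuple[int, int] = (4, 14)
    run_speed_mean: float = 30.0     # deg/s
    run_speed_sd: float = 4.0
    pause_duration_mean: float = 55.0  # s; task rewards encourage long pauses
    theta_freq: float = 8.0
    theta_bias: float = 0.0          # in [-1, 1]; forward sweep bias
    coupling_kappa: float = 1.0      # von Mises spike-gamma concentration
    swr_rate: float = 0.15           # events per second of pause
    swr_forward_prob: float = 0.7
    noise_rate: float = 0.2          # Hz uniform background per place cell
    unengaged_prob: float = 0.08     # fraction of laps without licking
    lick_rate: float = 5.0           # Hz while consuming reward
    n_channels: int = 4
    pyramidal_channel: int = 2       # channel with the ripple-power maximum
    theta_sweep_deg: float = 25.0    # half-extent of the within-cycle sweep
    bias_event_prob: float = 0.16    # nonlocal sweep episodes per cycle at |bias|=1
    bias_local_damp: float = 0.25    # local-rate factor inside an event episode
    bias_map_comp_deg: float = 6.0   # static counter-lead keeping rate maps centered
    place_field_kappa: float = 12.0  # von Mises tuning concentration
    place_peak_rate: float = 15.0    # Hz at the swept field center
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.track_zones * 18.0 != 360.0:
            raise ValueError("track zones must tile 360 degrees at 18 degrees")
        i, j = self.reward_zone_indices
        if abs(j - i) * 18.0 != 180.0:
            raise ValueError("reward zones must be 180 degrees apart")
        if not -1.0 <= self.theta_bias <= 1.0:
            raise ValueError("theta_bias must lie in [-1, 1]")
        if not 0.0 <= self.swr_forward_prob <= 1.0:
            raise ValueError("swr_forward_prob must lie in [0, 1]")
        for name in ("swr_rate", "noise_rate", "lick_rate", "coupling_kappa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def geometry(self) -> TrackGeometry:
        return TrackGeometry(
            n_zones=self.track_zones, reward_zone_indices=self.reward_zone_indices
        )


def generate_behavior(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[BehaviorTrace, dict]:
    """Simulate laps with pauses/licking at rewards; returns trace + truth."""
    rng = rng or np.random.default_rng(cfg.seed)
    geom = cfg.geometry
    dt = 1.0 / BEHAVIOR_RATE
    n = int(round(cfg.duration_s * BEHAVIOR_RATE))
    origin = geom.reward_zone_ends[0]
    pause_folded = FOLDED_TRACK_DEG - geom.zone_width_deg / 2  # mid reward zone

    pos = np.empty(n)
    speed = np.empty(n)
    licks: list[float] = []
    rewards: list[float] = []
    lap_engaged: list[bool] = []
    lap_boundaries: list[float] = [0.0]

    folded = 0.0
    i = 0
    while i < n:
        engaged = bool(rng.random() >= cfg.unengaged_prob)
        lap_engaged.append(engaged)
        lap_speed = max(5.0, rng.normal(cfg.run_speed_mean, cfg.run_speed_sd))
        target = pause_folded if engaged else FOLDED_TRACK_DEG
        anticipatory_emitted = False
        # run segment
        while i < n and folded < target:
            v = max(1.5, lap_speed + rng.normal(0.0, 1.0))
            pos[i] = wrap_angle(origin + folded)
            speed[i] = v
            if (
                engaged
                and not anticipatory_emitted
                and FOLDED_TRACK_DEG - 1.5 * geom.zone_width_deg
                <= folded
                < FOLDED_TRACK_DEG - geom.zone_width_deg
                and rng.random() < 0.7
            ):
                licks.append(i * dt)
                anticipatory_emitted = True
            folded += v * dt
            i += 1
        if engaged and i < n:
            # pause and consume reward inside the reward zone
            pause = max(3.0, rng.normal(cfg.pause_duration_mean, 0.2 * cfg.pause_duration_mean))
            n_pause = min(int(round(pause * BEHAVIOR_RATE)), n - i)
            t_pause = i * dt
            licks.append(t_pause + 0.2)
            rewards.append(t_pause + 0.2)
            lick_window = min(3.0, n_pause * dt)
            t_l = 0.2
            while True:
                t_l += rng.exponential(1.0 / cfg.lick_rate)
                if t_l >= lick_window:
                    break
                licks.append(t_pause + t_l)
            pos[i : i + n_pause] = wrap_angle(origin + folded)
            speed[i : i + n_pause] = 0.0
            i += n_pause
            target = FOLDED_TRACK_DEG
            while i < n and folded < target:
                v = max(1.5, lap_speed + rng.normal(0.0, 1.0))
                pos[i] = wrap_angle(origin + folded)
                speed[i] = v
                folded += v * dt
                i += 1
        if folded >= FOLDED_TRACK_DEG:
            folded -= FOLDED_TRACK_DEG
            origin = wrap_angle(origin + FOLDED_TRACK_DEG)
            if i < n:
                lap_boundaries.append(i * dt)

    if not np.any(speed > 1.0):
        raise ValueError("behavior contains no running epochs")
    time = np.arange(n) * dt
    trace = BehaviorTrace(
        time=time,
        position=pos,
        speed=speed,
        licks=np.array(sorted(licks)),
        rewards=np.array(rewards),
    )
    truth = {"lap_engaged": lap_engaged, "lap_boundary_times": lap_boundaries}
    return trace, truth


def generate_lfp(
    cfg: SyntheticConfig,
    behavior: BehaviorTrace,
    rng: np.random.Generator | None = None,
) -> tuple[LfpChannelSet, dict]:
    """Theta-dominated running LFP, delta-dominated pauses, SWR bursts."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    fs = cfg.lfp_rate
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    running = behavior.speed_at(t) > 1.0

    theta_phase = 2 * np.pi * cfg.theta_freq * t
    theta_amp = np.where(running, 80.0, 4.0)
    delta_amp = np.where(running, 8.0, 40.0)
    beta_amp = np.where(running, 8.0, 10.0)
    base = (
        theta_amp * np.cos(theta_phase)
        + delta_amp * np.cos(2 * np.pi * 2.5 * t + 1.0)
        + beta_amp * np.cos(2 * np.pi * 20.0 * t + 2.0)
        + 10.0 * np.cos(2 * np.pi * GAMMA_FREQ * t)
    )

    # SWR bursts at Poisson times inside pauses
    pause_runs = _bool_runs(~running)
    swr_times: list[float] = []
    for a, b in pause_runs:
        span = (b - a) / fs
        if span < 2.0:
            continue
        n_ev = rng.poisson(cfg.swr_rate * span)
        times = np.sort(rng.uniform(a / fs + 0.5, b / fs - 0.5, size=n_ev))
        keep = []
        for tt in times:
            if not keep or tt - keep[-1] > 0.5:
                keep.append(float(tt))
        swr_times.extend(keep)
    ripple = np.zeros(n)
    sigma = 0.012
    for tt in swr_times:
        sl = slice(max(0, int((tt - 0.06) * fs)), min(n, int((tt + 0.06) * fs)))
        tseg = t[sl] - tt
        ripple[sl] += 80.0 * np.exp(-0.5 * (tseg / sigma) ** 2) * np.cos(
            2 * np.pi * RIPPLE_FREQ * tseg
        )

    gradient = _ripple_gradient(cfg.n_channels, cfg.pyramidal_channel)
    samples = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        samples[c] = base + gradient[c] * ripple + rng.normal(0.0, 5.0, size=n)
    lfp = LfpChannelSet(samples=samples, rate=fs)
    truth = {
        "swr_times": swr_times,
        "pyramidal_channel": cfg.pyramidal_channel,
        "theta_phase0": 0.0,
    }
    return lfp, truth


def _ripple_gradient(n_channels: int, peak: int) -> np.ndarray:
    idx = np.arange(n_channels)
    return 0.35 + 0.65 * np.exp(-0.5 * ((idx - peak) / 1.0) ** 2)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[~mask[edges]] + 1)
    stops = list(edges[mask[edges]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if len(mask) and mask[-1]:
        stops.append(len(mask))
    return list(zip(starts, stops))


def generate_spikes(
    cfg: SyntheticConfig,
    behavior: BehaviorTrace,
    lfp_truth: dict,
    rng: np.random.Generator | None = None,
) -> tuple[list[SpikeUnit], dict]:
    """Place-cell, interneuron, replay and background spikes with truth."""
    rng = rng or np.random.default_rng(cfg.seed + 2)
    if not np.any(behavior.speed > 1.0):
        raise ValueError("no running epochs; cannot place theta-driven spikes")
    geom = cfg.geometry
    dt = 1.0 / SPIKE_GRID_RATE
    n = int(round(cfg.duration_s * SPIKE_GRID_RATE))
    t = np.arange(n) * dt
    pos = behavior.position_at(t)
    running = behavior.speed_at(t) > 1.0

    # theta phase relative to the trough: LFP theta is cos(phi), so the
    # trough sits at phi = pi; psi = phi - pi wrapped into (-pi, pi]
    phi = 2 * np.pi * cfg.theta_freq * t
    psi = np.mod(phi - np.pi + np.pi, 2 * np.pi) - np.pi
    sweep = cfg.theta_sweep_deg * (psi / np.pi)
    # The static counter-lead keeps rate maps centered on the true fields:
    # event spikes (below) sit behind the participating cells' fields and
    # would otherwise drag every map backward by ~6 deg per unit |bias|.
    # A static lead is itself absorbed by map calibration, so it has no
    # decode-time footprint of its own.
    represented = np.mod(
        pos + sweep - cfg.theta_bias * cfg.bias_map_comp_deg, 360.0
    )
    # Prospective/retrospective bias: coordinated nonlocal sweep events.
    # A static phase offset added to the local sweep self-cancels (rate
    # maps trained on the same spikes absorb any per-cell lead and the
    # decoder re-centers it away), and independent-Poisson lookahead
    # spiking is filtered out by the 2-spikes-per-bin decoding minimum.
    # What survives calibration is what real prospective theta content is:
    # occasional half-cycles in which an assembly of cells with fields
    # 12-45 degrees ahead (behind, for negative bias) fires coordinated
    # bursts while local firing is damped. Each cell's event spikes spread
    # over a wide span of positions away from its field, so its rate map
    # only gains a diffuse tail.
    centers = np.sort(
        np.mod(
            np.linspace(0.0, 360.0, cfg.n_place_cells, endpoint=False)
            + rng.uniform(-3.0, 3.0, cfg.n_place_cells),
            360.0,
        )
    )

    b = cfg.theta_bias
    suppress = np.ones(n)
    event_spikes: dict[int, list[float]] = {}
    if b != 0.0:
        cycle = 1.0 / cfg.theta_freq
        trough_times = (0.5 + np.arange(int(cfg.duration_s * cfg.theta_freq))) / cfg.theta_freq
        tr_idx = np.clip((trough_times * SPIKE_GRID_RATE).astype(int), 0, n - 1)
        trough_times = trough_times[running[tr_idx]]
        for t_k in trough_times:
            if rng.random() >= abs(b) * cfg.bias_event_prob:
                continue
            # one full cycle of sustained nonlocal representation starting
            # at the trough: ahead of the animal for positive bias, behind
            # for negative bias
            t0 = t_k
            p_k = float(behavior.position_at(np.array([t_k]))[0])
            rel = circ_diff(centers, p_k)
            if b > 0:
                members = np.flatnonzero((rel >= 12.0) & (rel <= 45.0))
                order = members[np.argsort(rel[members])]
            else:
                members = np.flatnonzero((rel <= -12.0) & (rel >= -45.0))
                order = members[np.argsort(-rel[members])]
            if len(order) == 0:
                continue
            i0, i1 = int(t0 * SPIKE_GRID_RATE), int((t0 + cycle) * SPIKE_GRID_RATE)
            suppress[max(i0, 0) : min(i1, n)] = cfg.bias_local_damp
            # each member emits two 2-spike bursts spread over the episode,
            # so most 20 ms windows reach the decoder's spike minimum
            slots = np.concatenate([order, order])
            for j, cell in enumerate(slots):
                t_burst = t0 + (j + 0.5) / len(slots) * cycle + rng.normal(0.0, 0.002)
                event_spikes.setdefault(int(cell), []).extend(
                    [t_burst, t_burst + 0.005]
                )

    kappa_tune = cfg.place_field_kappa
    width_deg = 2 * np.degrees(np.arccos(1 - 1 / kappa_tune))

    units: list[SpikeUnit] = []
    regions = ["CA1" if k % 3 else "CA3" for k in range(cfg.n_place_cells)]
    for k in range(cfg.n_place_cells):
        ang = np.deg2rad(represented - centers[k])
        lam = cfg.place_peak_rate * np.exp(kappa_tune * (np.cos(ang) - 1.0)) * suppress
        lam = np.where(running, lam, 0.0) + cfg.noise_rate
        spikes = t[rng.random(n) < lam * dt]
        if cfg.coupling_kappa > 0 and len(spikes):
            spikes = _couple_to_gamma(spikes, cfg.coupling_kappa, rng)
        if k in event_spikes:
            # event bursts keep their fine timing (they carry sequence content)
            spikes = np.sort(np.concatenate([spikes, event_spikes[k]]))
        units.append(
            SpikeUnit(
                unit_id=k,
                region=regions[k],
                spike_times=spikes,
                spike_width_ms=rng.uniform(0.6, 0.9),
                acg_first_moment_ms=rng.uniform(2.0, 4.0),
                snr=rng.uniform(2.0, 6.0),
                refractory_violation_frac=rng.uniform(0.0, 0.004),
            )
        )

    # replay spikes inside each synthetic ripple
    directions: list[str] = []
    for tt in lfp_truth.get("swr_times", []):
        p = float(behavior.position_at(np.array([tt]))[0])
        forward = bool(rng.random() < cfg.swr_forward_prob)
        directions.append("forward" if forward else "reverse")
        rel = circ_diff(centers, p)
        if forward:
            members = np.flatnonzero((rel >= 9.0) & (rel <= 63.0))
            order = members[np.argsort(rel[members])]
        else:
            members = np.flatnonzero((rel <= -9.0) & (rel >= -63.0))
            order = members[np.argsort(-rel[members])]
        lag = rng.uniform(0.004, 0.008)
        start = tt - 0.5 * lag * max(len(order) - 1, 0)
        for j, cell in enumerate(order):
            st = units[cell].spike_times
            units[cell].spike_times = np.sort(np.append(st, start + j * lag))

    # non-spatial pyramidal cells: uniform firing, should fail the SI gate
    n_ns = cfg.n_nonspatial_cells
    for k in range(n_ns):
        spikes = t[rng.random(n) < 1.5 * dt]
        if cfg.coupling_kappa > 0 and len(spikes):
            spikes = _couple_to_gamma(spikes, cfg.coupling_kappa, rng)
        units.append(
            SpikeUnit(
                unit_id=cfg.n_place_cells + k,
                region="CA1" if k % 2 else "CA3",
                spike_times=spikes,
                spike_width_ms=rng.uniform(0.6, 0.9),
                acg_first_moment_ms=rng.uniform(2.0, 4.0),
                snr=rng.uniform(2.0, 6.0),
                refractory_violation_frac=rng.uniform(0.0, 0.004),
            )
        )

    for k in range(cfg.n_interneurons):
        spikes = t[rng.random(n) < 15.0 * dt]
        if cfg.coupling_kappa > 0 and len(spikes):
            spikes = _couple_to_gamma(spikes, cfg.coupling_kappa, rng)
        units.append(
            SpikeUnit(
                unit_id=cfg.n_place_cells + n_ns + k,
                region="CA3" if k % 2 else "CA1",
                spike_times=spikes,
                spike_width_ms=rng.uniform(0.2, 0.4),
                acg_first_moment_ms=rng.uniform(5.5, 8.0),
                snr=rng.uniform(2.0, 6.0),
                refractory_violation_frac=rng.uniform(0.0, 0.004),
            )
        )

    truth = {
        "field_centers": centers.tolist(),
        "field_width_deg": float(width_deg),
        "true_theta_bias": cfg.theta_bias,
        "true_kappa": cfg.coupling_kappa,
        "true_swr_directions": directions,
        "place_cell_ids": list(range(cfg.n_place_cells)),
        "nonspatial_ids": list(range(cfg.n_place_cells, cfg.n_place_cells + n_ns)),
        "interneuron_ids": list(
            range(cfg.n_place_cells + n_ns, cfg.n_place_cells + n_ns + cfg.n_interneurons)
        ),
    }
    return units, truth


def _couple_to_gamma(
    spikes: np.ndarray, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Nudge each spike to the nearest time where the embedded slow-gamma
    phase equals a von Mises draw, giving the requested concentration."""
    target = rng.vonmises(0.0, kappa, size=len(spikes))
    current = np.mod(2 * np.pi * GAMMA_FREQ * spikes + np.pi, 2 * np.pi) - np.pi
    delta = np.mod(target - current + np.pi, 2 * np.pi) - np.pi
    return np.sort(spikes + delta / (2 * np.pi * GAMMA_FREQ))


def generate_session(cfg: SyntheticConfig) -> Session:
    """Full synthetic session: behavior, LFP, spikes and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    behavior, beh_truth = generate_behavior(cfg, rng)
    lfp, lfp_truth = generate_lfp(cfg, behavior, rng)
    units, spike_truth = generate_spikes(cfg, behavior, lfp_truth, rng)
    truth = {**beh_truth, **lfp_truth, **spike_truth}
    return Session(
        behavior=behavior,
        lfp=lfp,
        units=units,
        geometry=cfg.geometry,
        ground_truth=truth,
    )
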