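"""Memoryless Bayesian position decoding with a Poisson spiking model.

For spike counts S_i of N cells in a window of length tau and rate maps
f_i(theta), the posterior over position bins (flat prior) is

    P(theta | S) ∝ prod_i (tau f_i(theta))^{S_i} * exp(-tau sum_i f_i(theta))

normalized to sum to 1 over bins. Computation is in log space; rate maps
are floored at a small positive rate so a single stray spike cannot
annihilate the posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import Trial
from .config import PipelineConfig
from .geometry import BinGeometry, circ_dist
from .session import BehaviorTrace, SpikeUnit


@dataclass
class DecodedWindow:
    """Posterior (n_time_bins, n_pos_bins); undecoded bins are NaN rows."""

    time_edges: np.ndarray
    posterior: np.ndarray
    n_spikes: np.ndarray
    tau: float
    bins: BinGeometry
    decoded: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.decoded is None:
            self.decoded = ~np.isnan(self.posterior).any(axis=1)


def rate_matrix(
    rate_maps: dict[int, "np.ndarray | object"], unit_ids: list[int]
) -> np.ndarray:
    """Stack rate maps (cells x bins), accepting RateMap objects or arrays."""
    rows = []
    for uid in unit_ids:
        rm = rate_maps[uid]
        rows.append(np.asarray(getattr(rm, "rates", rm), dtype=float))
    return np.array(rows)


def decode_window(
    spike_counts: np.ndarray,
    rates: np.ndarray,
    tau: float,
    cfg: PipelineConfig | None = None,
) -> np.ndarray:
    """Posterior over position bins for one time window.

    ``spike_counts``: (n_cells,) counts; ``rates``: (n_cells, n_bins) Hz.
    """
    cfg = cfg or PipelineConfig()
    s = np.asarray(spike_counts, dtype=float)
    f = np.maximum(np.asarray(rates, dtype=float), cfg.rate_floor_hz)
    log_post = s @ np.log(tau * f) - tau * f.sum(axis=0)
    log_post -= log_post.max()
    post = np.exp(log_post)
    total = post.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("posterior vanished; check rate maps")
    return post / total


def decode_windows(
    spike_times_by_unit: list[np.ndarray],
    rates: np.ndarray,
    time_edges: np.ndarray,
    tau: float,
    bins: BinGeometry,
    min_spikes: int | None = None,
    cfg: PipelineConfig | None = None,
) -> DecodedWindow:
    """Decode consecutive windows; windows under the spike minimum are NaN."""
    cfg = cfg or PipelineConfig()
    min_spikes = cfg.decode_min_spikes if min_spikes is None else min_spikes
    n_t = len(time_edges) - 1
    if not spike_times_by_unit:
        raise ValueError("no units supplied to decoder")
    counts = np.array(
        [np.histogram(st, bins=time_edges)[0] for st in spike_times_by_unit]
    )
    totals = counts.sum(axis=0)
    posterior = np.full((n_t, bins.n_bins), np.nan)
    for k in range(n_t):
        if totals[k] >= min_spikes:
            posterior[k] = decode_window(counts[:, k], rates, tau, cfg)
    return DecodedWindow(
        time_edges=np.asarray(time_edges, dtype=float),
        posterior=posterior,
        n_spikes=totals,
        tau=tau,
        bins=bins,
    )


@dataclass
class CrossValidatedDecoding:
    """Per-block decoding results pooled over cross-validation folds."""

    block_times: np.ndarray      # block centers, s
    actual_position: np.ndarray  # folded degrees per decoded block
    map_estimate: np.ndarray     # argmax position per decoded block
    error_deg: np.ndarray        # circular decoding error per block
    posterior_at_actual: np.ndarray
    n_bins: int
    fold_of_block: np.ndarray

    @property
    def median_error(self) -> float:
        return float(np.median(self.error_deg)) if len(self.error_deg) else np.nan

    @property
    def normalized_prob(self) -> float:
        """Mean posterior at the true bin, scaled so chance = 1."""
        if len(self.posterior_at_actual) == 0:
            return np.nan
        return float(np.mean(self.posterior_at_actual) * self.n_bins)


def cross_validated_decode(
    units: list[SpikeUnit],
    behavior: BehaviorTrace,
    trials: list[Trial],
    track,
    cfg: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CrossValidatedDecoding:
    """5-fold cross-validated decoding of current position on correct trials.

    Folds partition correct trials at random; rate maps (folded geometry,
    3-degree bins) are trained on the other folds' trials and 200 ms blocks
    with at least 2 spikes are decoded on the held-out trials. Blocks are
    restricted to movement (speed above the place-field threshold): during
    reward pauses the animal's "current position" is not being expressed in
    place-cell spiking, and immobile content is analyzed by the ripple
    pipeline instead.
    """
    from .placefields import MapBuilder

    cfg = cfg or PipelineConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    correct = [t for t in trials if t.label == "correct"]
    if len(correct) < cfg.n_folds:
        raise ValueError(f"need at least {cfg.n_folds} correct trials")
    order = rng.permutation(len(correct))
    folds = np.array_split(order, cfg.n_folds)

    prev_est: float | None = None
    rows = {k: [] for k in ("t", "actual", "est", "err", "p_act", "fold")}
    for fi, test_idx in enumerate(folds):
        train_trials = [correct[i] for i in order if i not in set(test_idx)]
        train_intervals = [(t.start_s, t.end_s) for t in train_trials]
        builder = MapBuilder(
            behavior, track, folded=True, cfg=cfg, intervals=train_intervals
        )
        rates = np.array(
            [builder.rate_map(u.spike_times).rates for u in units]
        )
        bins = builder.bins
        for ti in test_idx:
            tr = correct[ti]
            edges = np.arange(tr.start_s, tr.end_s, cfg.decode_tau_s)
            if len(edges) < 2:
                continue
            spike_trains = [
                u.spike_times[(u.spike_times >= tr.start_s) & (u.spike_times < tr.end_s)]
                for u in units
            ]
            dec = decode_windows(
                spike_trains, rates, edges, cfg.decode_tau_s, bins, cfg=cfg
            )
            centers = 0.5 * (edges[:-1] + edges[1:])
            actual = track.fold(behavior.position_at(centers))
            moving = behavior.speed_at(centers) > cfg.movement_speed_min
            for k in range(len(centers)):
                if not dec.decoded[k] or not moving[k]:
                    continue
                post = dec.posterior[k]
                est = _argmax_position(post, bins, prev_est)
                prev_est = est
                err = float(circ_dist(est, actual[k], period=bins.span_deg))
                rows["t"].append(centers[k])
                rows["actual"].append(actual[k])
                rows["est"].append(est)
                rows["err"].append(err)
                rows["p_act"].append(post[bins.bin_index(np.array([actual[k]]))[0]])
                rows["fold"].append(fi)
    return CrossValidatedDecoding(
        block_times=np.array(rows["t"]),
        actual_position=np.array(rows["actual"]),
        map_estimate=np.array(rows["est"]),
        error_deg=np.array(rows["err"]),
        posterior_at_actual=np.array(rows["p_act"]),
        n_bins=60,
        fold_of_block=np.array(rows["fold"], dtype=int),
    )


def _argmax_position(post: np.ndarray, bins: BinGeometry, prev: float | None) -> float:
    """Argmax bin center; ties go to the bin nearest the previous estimate."""
    best = post.max()
    tied = np.flatnonzero(post >= best - 1e-15)
    if len(tied) == 1 or prev is None:
        return float(bins.centers[tied[0]])
    d = circ_dist(bins.centers[tied], prev, period=bins.span_deg)
    return float(bins.centers[tied[np.argmin(d)]])


def session_qc(decoded: CrossValidatedDecoding, cfg: PipelineConfig | None = None) -> bool:
    """Keep sessions whose normalized true-bin posterior is at least 1.2."""
    cfg = cfg or PipelineConfig()
    return bool(decoded.normalized_prob >= cfg.qc_min_normalized_prob)
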