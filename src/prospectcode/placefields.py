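"""Occupancy-normalized rate maps, place-cell identification and properties.

Rate maps bin spikes and occupancy over position (full track, 2-degree
bins, or the folded distance-to-reward axis, 3-degree bins), keep only
moving samples (speed > 1 deg/s), smooth both maps with a circularly
wrapped Gaussian (SD 2 bins) and divide. Spatial information per spike is

    SI = sum_i p_i (lambda_i / lambda) log2(lambda_i / lambda)

with occupancy probabilities p_i and mean rate lambda = sum_i p_i lambda_i.
Significance comes from a circular time-shift shuffle: spike times are
permuted by random offsets in [20 s, T] and wrapped (per spike by default,
whole-train as an option), which destroys the place code; a cell is a
place cell when its SI exceeds the shuffle 95th percentile and its mean
rate is in [0.2, 10] Hz with peak rate >= 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .geometry import BinGeometry, FOLDED_BINS, FULL_TRACK_BINS, TrackGeometry
from .session import BehaviorTrace, SpikeUnit


@dataclass
class RateMap:
    rates: np.ndarray          # Hz per bin
    occupancy: np.ndarray      # raw seconds per bin (movement-filtered)
    bins: BinGeometry
    folded: bool
    included: np.ndarray       # bins with enough occupancy for SI

    @property
    def peak_rate(self) -> float:
        return float(self.rates.max())

    @property
    def peak_position(self) -> float:
        """Bin center of the maximum rate; ties break to the lowest angle."""
        return float(self.bins.centers[int(np.argmax(self.rates))])

    @property
    def mean_rate(self) -> float:
        """Plain average of the occupancy-normalized map."""
        return float(self.rates.mean())


@dataclass
class PlaceCellRecord:
    unit_id: int
    region: str
    is_place_cell: bool
    spatial_info: float
    shuffle_p95: float
    mean_rate: float
    peak_rate: float
    peak_position: float
    sparsity: float = np.nan
    in_reward_related_zone: bool = False


def _gaussian_kernel(sd_bins: float) -> np.ndarray:
    half = int(np.ceil(4 * sd_bins))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sd_bins) ** 2)
    return k / k.sum()


def circular_smooth(x: np.ndarray, sd_bins: float) -> np.ndarray:
    """Gaussian smoothing with wrap-around, kernel truncated at +/- 4 SD."""
    if sd_bins <= 0:
        return np.asarray(x, dtype=float)
    k = _gaussian_kernel(sd_bins)
    half = len(k) // 2
    xp = np.concatenate([x[-half:], x, x[:half]])
    return np.convolve(xp, k, mode="valid")


class MapBuilder:
    """Caches the movement-filtered occupancy so shuffles only re-bin spikes."""

    def __init__(
        self,
        behavior: BehaviorTrace,
        track: TrackGeometry,
        bins: BinGeometry | None = None,
        folded: bool = False,
        cfg: PipelineConfig | None = None,
        intervals: list[tuple[float, float]] | None = None,
    ):
        self.cfg = cfg or PipelineConfig()
        self.track = track
        self.folded = folded
        self.bins = bins or (FOLDED_BINS if folded else FULL_TRACK_BINS)
        self.behavior = behavior
        self.intervals = intervals

        moving = behavior.speed > self.cfg.movement_speed_min
        if intervals is not None:
            moving &= _in_any_interval(behavior.time, intervals)
        coord = track.fold(behavior.position) if folded else behavior.position
        dt = np.empty_like(behavior.time)
        dt[:-1] = np.diff(behavior.time)
        dt[-1] = dt[-2] if len(dt) > 1 else 0.0
        # gaps (e.g. concatenated trial segments) must not inflate one bin
        dt = np.minimum(dt, 2.0 * np.median(dt))
        occ = np.zeros(self.bins.n_bins)
        np.add.at(occ, self.bins.bin_index(coord[moving]), dt[moving])
        self.occupancy = occ
        self.occupancy_smooth = circular_smooth(occ, self.cfg.ratemap_smooth_sd_bins)
        self.included = occ >= self.cfg.min_occupancy_s

    def spike_counts(self, spike_times: np.ndarray) -> np.ndarray:
        st = np.asarray(spike_times, dtype=float)
        st = st[(st >= self.behavior.time[0]) & (st <= self.behavior.time[-1])]
        if self.intervals is not None and len(st):
            st = st[_in_any_interval(st, self.intervals)]
        if len(st) == 0:
            return np.zeros(self.bins.n_bins)
        moving = self.behavior.speed_at(st) > self.cfg.movement_speed_min
        st = st[moving]
        pos = self.behavior.position_at(st)
        coord = self.track.fold(pos) if self.folded else pos
        counts = np.zeros(self.bins.n_bins)
        np.add.at(counts, self.bins.bin_index(coord), 1.0)
        return counts

    def rate_map(self, spike_times: np.ndarray) -> RateMap:
        if self.occupancy.sum() <= 0:
            raise ValueError("zero total occupancy under the movement filter")
        counts = circular_smooth(
            self.spike_counts(spike_times), self.cfg.ratemap_smooth_sd_bins
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(self.occupancy_smooth > 0, counts / self.occupancy_smooth, 0.0)
        rates = np.where(self.included, rates, 0.0)
        return RateMap(
            rates=rates,
            occupancy=self.occupancy,
            bins=self.bins,
            folded=self.folded,
            included=self.included,
        )


def _in_any_interval(t: np.ndarray, intervals) -> np.ndarray:
    mask = np.zeros(len(t), dtype=bool)
    for a, b in intervals:
        mask |= (t >= a) & (t < b)
    return mask


def occupancy_rate_map(
    unit: SpikeUnit,
    behavior: BehaviorTrace,
    track: TrackGeometry,
    folded: bool = False,
    cfg: PipelineConfig | None = None,
) -> RateMap:
    return MapBuilder(behavior, track, folded=folded, cfg=cfg).rate_map(unit.spike_times)


def spatial_information(rate_map: RateMap) -> float:
    """Spatial information in bits per spike over included bins."""
    occ = rate_map.occupancy[rate_map.included]
    lam = rate_map.rates[rate_map.included]
    if occ.sum() <= 0:
        raise ValueError("empty occupancy")
    p = occ / occ.sum()
    mean_rate = float(np.sum(p * lam))
    if mean_rate <= 0:
        raise ValueError("all-zero rate map")
    rel = lam / mean_rate
    terms = np.where(rel > 0, p * rel * np.log2(np.where(rel > 0, rel, 1.0)), 0.0)
    return float(terms.sum())


def shuffle_null(
    unit: SpikeUnit,
    builder: MapBuilder,
    n_shuffles: int | None = None,
    rng: np.random.Generator | None = None,
    mode: str | None = None,
) -> np.ndarray:
    """Null SI distribution from circular time shifts of the spike train.

    ``per_spike`` (default) draws an independent circular shift per spike;
    ``whole_train`` applies one shift per shuffle to the entire train,
    which preserves ISI structure but degenerates on sessions dominated by
    long immobile pauses (few coherent bursts survive the movement filter,
    leaving sharp fake fields in the null).
    """
    cfg = builder.cfg
    mode = mode or cfg.shuffle_mode
    n = n_shuffles if n_shuffles is not None else cfg.n_shuffles
    rng = rng or np.random.default_rng(cfg.seed)
    t0, t1 = builder.behavior.time[0], builder.behavior.time[-1]
    length = t1 - t0
    if length <= cfg.shuffle_min_shift_s:
        raise ValueError("session shorter than the minimum shuffle shift")
    st = unit.spike_times
    out = np.empty(n)
    for i in range(n):
        if mode == "whole_train":
            shift = rng.uniform(cfg.shuffle_min_shift_s, length)
        elif mode == "per_spike":
            shift = rng.uniform(cfg.shuffle_min_shift_s, length, size=len(st))
        else:
            raise ValueError(f"unknown shuffle mode {mode!r}")
        shifted = t0 + np.mod(st - t0 + shift, length)
        rm = builder.rate_map(shifted)
        # a shuffle can land every spike outside movement: no information
        out[i] = spatial_information(rm) if rm.rates.sum() > 0 else 0.0
    return out


def classify_place_cell(
    spatial_info: float,
    shuffle_p95: float,
    mean_rate: float,
    peak_rate: float,
    cfg: PipelineConfig | None = None,
) -> bool:
    cfg = cfg or PipelineConfig()
    return bool(
        spatial_info > shuffle_p95
        and mean_rate >= cfg.place_min_mean_rate
        and mean_rate <= cfg.place_max_mean_rate
        and peak_rate >= cfg.place_min_peak_rate
    )


def sparsity(rate_map: RateMap) -> float:
    """Occupancy-map sparsity with small-sample correction, in [0, 1].

    S = [1 - (sum(lam)/L)^2 / (sum(lam^2)/L)] * L/(L-1); 0 for a uniform
    map, 1 for firing confined to a single bin.
    """
    lam = rate_map.rates
    L = len(lam)
    sq = float(np.sum(lam**2))
    if sq <= 0:
        raise ValueError("all-zero rate map")
    s = (1.0 - (lam.sum() / L) ** 2 / (sq / L)) * L / (L - 1)
    return float(np.clip(s, 0.0, 1.0))


def field_properties(rate_map: RateMap, track: TrackGeometry) -> dict:
    """Peak/mean rates, peak position, and reward-related membership."""
    peak_pos = rate_map.peak_position
    if rate_map.folded:
        from .geometry import FOLDED_TRACK_DEG

        reward_related = peak_pos >= FOLDED_TRACK_DEG - 2 * track.zone_width_deg
    else:
        reward_related = bool(track.in_reward_related_zones(np.array([peak_pos]))[0])
    degenerate = bool(np.all(rate_map.rates == rate_map.rates[0]))
    return {
        "peak_rate": rate_map.peak_rate,
        "peak_position": peak_pos,
        "mean_rate": rate_map.mean_rate,
        "in_reward_related_zone": reward_related,
        "degenerate": degenerate,
    }


def identify_place_cells(
    units: list[SpikeUnit],
    behavior: BehaviorTrace,
    track: TrackGeometry,
    cfg: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
    n_shuffles: int | None = None,
) -> tuple[list[PlaceCellRecord], dict[int, RateMap]]:
    """Classify pyramidal units on full-track maps; folded maps for the kept cells.

    Returns per-unit records plus folded (distance-to-reward) rate maps for
    the identified place cells.
    """
    cfg = cfg or PipelineConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    full = MapBuilder(behavior, track, folded=False, cfg=cfg)
    foldb = MapBuilder(behavior, track, folded=True, cfg=cfg)
    records = []
    folded_maps: dict[int, RateMap] = {}
    for u in units:
        if u.n_spikes < 2:
            continue
        rm = full.rate_map(u.spike_times)
        if rm.rates.sum() <= 0:
            continue
        si = spatial_information(rm)
        null = shuffle_null(u, full, n_shuffles=n_shuffles, rng=rng)
        p95 = float(np.percentile(null, 95))
        is_pc = classify_place_cell(si, p95, rm.mean_rate, rm.peak_rate, cfg)
        rec = PlaceCellRecord(
            unit_id=u.unit_id,
            region=u.region,
            is_place_cell=is_pc,
            spatial_info=si,
            shuffle_p95=p95,
            mean_rate=rm.mean_rate,
            peak_rate=rm.peak_rate,
            peak_position=rm.peak_position,
        )
        if is_pc:
            fm = foldb.rate_map(u.spike_times)
            folded_maps[u.unit_id] = fm
            rec.sparsity = sparsity(fm)
            props = field_properties(fm, track)
            rec.in_reward_related_zone = props["in_reward_related_zone"]
        records.append(rec)
    return records, folded_maps


def place_cell_table(records: list[PlaceCellRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
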