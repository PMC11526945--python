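"""Sharp-wave-ripple content: prospective ratio, sequence-less decoding,
unoccupied-zone detection, and place-cell (co)activation.

Spiking in a 250 ms window around each ripple midpoint is decoded in 25 ms
bins (bins with more than one spike) and re-centered on the animal. The
prospective coding ratio is (F - B)/(F + B) where F sums posterior mass
over +9..+63 degrees ahead and B over -9..-63 degrees behind; the local
+/-9 degree band (one track zone) and the +/-63..90 degree edges are
excluded. Events with ratio > 0.1 count as prospective-coding SWRs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .decoding import decode_windows
from .geometry import BinGeometry, circ_diff
from .session import SwrEvent
from .theta import recenter_posterior, unoccupied_zone_flag


@dataclass
class SwrDecoding:
    event_id: int
    midpoint_s: float
    posterior: np.ndarray      # (n_time_bins, n_rel_bins), NaN rows undecoded
    rel_centers: np.ndarray
    time_centers: np.ndarray
    animal_position: float
    in_reward_zone: bool
    prospective_ratio: float = np.nan
    ratio_defined: bool = False

    @property
    def decoded(self) -> np.ndarray:
        return ~np.isnan(self.posterior).any(axis=1)

    @property
    def n_decoded_bins(self) -> int:
        return int(self.decoded.sum())


def decode_swr(
    event: SwrEvent,
    event_id: int,
    spike_times_by_unit: list[np.ndarray],
    rates: np.ndarray,
    bins: BinGeometry,
    animal_position: float,
    in_reward_zone: bool,
    cfg: PipelineConfig | None = None,
) -> SwrDecoding | None:
    """Decode one SWR window; None when no bin has more than one spike."""
    cfg = cfg or PipelineConfig()
    half = cfg.swr_window_s / 2
    mid = event.midpoint_s
    edges = mid + np.arange(-half, half + cfg.swr_bin_s / 2, cfg.swr_bin_s)
    dec = decode_windows(
        spike_times_by_unit, rates, edges, cfg.swr_bin_s, bins,
        min_spikes=cfg.swr_min_bin_spikes, cfg=cfg,
    )
    if not dec.decoded.any():
        return None
    post, rel = recenter_posterior(dec.posterior, bins, animal_position)
    out = SwrDecoding(
        event_id=event_id,
        midpoint_s=mid,
        posterior=post,
        rel_centers=rel,
        time_centers=0.5 * (edges[:-1] + edges[1:]) - mid,
        animal_position=animal_position,
        in_reward_zone=in_reward_zone,
    )
    out.prospective_ratio, out.ratio_defined = swr_prospective_ratio(out, cfg)
    return out


def _window_masks(rel_centers: np.ndarray, cfg: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = cfg.swr_local_exclusion_deg, cfg.swr_far_window_deg
    forward = (rel_centers > lo) & (rel_centers <= hi)
    behind = (rel_centers < -lo) & (rel_centers >= -hi)
    return forward, behind


def swr_prospective_ratio(
    decoding: SwrDecoding, cfg: PipelineConfig | None = None
) -> tuple[float, bool]:
    """(F - B)/(F + B) summed over decoded bins; undefined when F + B = 0."""
    cfg = cfg or PipelineConfig()
    forward, behind = _window_masks(decoding.rel_centers, cfg)
    post = decoding.posterior[decoding.decoded]
    f = float(np.nansum(post[:, forward]))
    b = float(np.nansum(post[:, behind]))
    if f + b <= 0:
        return np.nan, False
    return (f - b) / (f + b), True


def fraction_prospective(
    decodings: list[SwrDecoding], cfg: PipelineConfig | None = None
) -> float:
    """Fraction of events with prospective ratio above 0.1."""
    cfg = cfg or PipelineConfig()
    ratios = [d.prospective_ratio for d in decodings if d.ratio_defined]
    if not ratios:
        raise ValueError("no events with a defined prospective ratio")
    return float(np.mean(np.asarray(ratios) > cfg.prospective_swr_threshold))


def sequenceless_decode(
    event: SwrEvent,
    spike_times_by_unit: list[np.ndarray],
    rates: np.ndarray,
    bins: BinGeometry,
    animal_position: float,
    cfg: PipelineConfig | None = None,
) -> tuple[float, bool] | None:
    """Single-bin decode over the whole event; relative argmax position.

    tau is the actual event duration. Returns (relative position of the
    posterior maximum in degrees, degenerate flag) or None when the event
    has fewer than 2 spikes.
    """
    cfg = cfg or PipelineConfig()
    edges = np.array([event.start_s, event.end_s])
    tau = event.end_s - event.start_s
    dec = decode_windows(
        spike_times_by_unit, rates, edges, tau, bins,
        min_spikes=cfg.swr_min_bin_spikes, cfg=cfg,
    )
    if not dec.decoded[0]:
        return None
    post = dec.posterior[0]
    degenerate = bool(np.allclose(post, post[0]))
    est = float(bins.centers[int(np.argmax(post))])
    rel = float(circ_diff(est, animal_position, period=bins.span_deg))
    return rel, degenerate


def unoccupied_zone_swr(
    decoding_fulltrack: SwrDecoding, cfg: PipelineConfig | None = None
) -> tuple[bool, bool]:
    """Far-zone (180 deg away, one-zone width) decoding flag for one event.

    Uses the same 2-SD rule as the theta analysis, with the far zone one
    18-degree track zone centered opposite the animal (162-198 deg away).
    """
    cfg = cfg or PipelineConfig()
    avg = decoding_fulltrack.posterior[decoding_fulltrack.decoded]
    if avg.size == 0:
        return False, True
    return unoccupied_zone_flag(avg, decoding_fulltrack.rel_centers, cfg)


def activation_coactivation(
    unit_ids: list[int],
    spike_times_by_unit: list[np.ndarray],
    events: list[SwrEvent],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell activation and per-pair coactivation probabilities.

    activation(c) = #{events in which c fires >= 1 spike} / #events;
    coactivation(c1, c2) likewise for both cells firing, unordered pairs.
    """
    if not events:
        raise ValueError("no SWR events")
    n_ev = len(events)
    fired = np.zeros((len(unit_ids), n_ev), dtype=bool)
    for i, st in enumerate(spike_times_by_unit):
        st = np.asarray(st)
        for j, ev in enumerate(events):
            fired[i, j] = bool(np.any((st >= ev.start_s) & (st <= ev.end_s)))
    act = pd.DataFrame(
        {"unit_id": unit_ids, "activation": fired.mean(axis=1), "n_events": n_ev}
    )
    rows = []
    for i in range(len(unit_ids)):
        for j in range(i + 1, len(unit_ids)):
            rows.append(
                {
                    "unit_a": unit_ids[i],
                    "unit_b": unit_ids[j],
                    "coactivation": float(np.mean(fired[i] & fired[j])),
                    "n_events": n_ev,
                }
            )
    return act, pd.DataFrame(rows, columns=["unit_a", "unit_b", "coactivation", "n_events"])


def swr_event_table(decodings: list[SwrDecoding]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [d.event_id for d in decodings],
            "midpoint_s": [d.midpoint_s for d in decodings],
            "position_deg": [d.animal_position for d in decodings],
            "in_reward_zone": [d.in_reward_zone for d in decodings],
            "n_decoded_bins": [d.n_decoded_bins for d in decodings],
            "prospective_ratio": [d.prospective_ratio for d in decodings],
            "ratio_defined": [d.ratio_defined for d in decodings],
        }
    )
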