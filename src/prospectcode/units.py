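"""Unit inclusion criteria and pyramidal/interneuron classification.

Units are kept when they have < 0.8% refractory-period (1 ms) violations
and peak SNR >= 1. Putative pyramidal cells have broad spikes (width >
0.5 ms) with a short-latency autocorrelogram (first moment < 4.5 ms);
putative interneurons the reverse; anything else stays unclassified.
"""

from __future__ import annotations

import warnings

import numpy as np

from .config import PipelineConfig
from .session import SpikeUnit


def quality_filter(units: list[SpikeUnit], cfg: PipelineConfig | None = None) -> list[SpikeUnit]:
    """Units passing the refractory-violation and SNR inclusion criteria."""
    cfg = cfg or PipelineConfig()
    kept = []
    for u in units:
        if np.isnan(u.refractory_violation_frac) or np.isnan(u.snr):
            warnings.warn(f"unit {u.unit_id}: missing quality metadata; excluded")
            continue
        if u.refractory_violation_frac < cfg.max_refractory_violation and u.snr >= cfg.min_snr:
            kept.append(u)
    return kept


def classify_cell_type(unit: SpikeUnit, cfg: PipelineConfig | None = None) -> str:
    """Classify a unit from spike width and autocorrelogram first moment.

    Both comparisons are strict, so boundary values fall into
    "unclassified".
    """
    cfg = cfg or PipelineConfig()
    w, m = unit.spike_width_ms, unit.acg_first_moment_ms
    if w > cfg.pyramidal_min_width_ms and m < cfg.pyramidal_max_acg_moment_ms:
        return "pyramidal"
    if w < cfg.pyramidal_min_width_ms and m > cfg.pyramidal_max_acg_moment_ms:
        return "interneuron"
    return "unclassified"


def classify_units(units: list[SpikeUnit], cfg: PipelineConfig | None = None) -> list[SpikeUnit]:
    for u in units:
        u.cell_type = classify_cell_type(u, cfg)
    return units


def acg_first_moment(spike_times: np.ndarray, max_lag_ms: float = 50.0) -> float:
    """First moment (ms) of the positive-lag spike autocorrelogram.

    Mean positive inter-spike lag up to ``max_lag_ms``, zero lag excluded.
    Computed from the exact lags rather than 1 ms histogram centers to
    avoid the half-bin offset.
    """
    t = np.sort(np.asarray(spike_times, dtype=float))
    if len(t) < 2:
        raise ValueError("need at least two spikes")
    max_lag = max_lag_ms / 1000.0
    total = 0.0
    count = 0
    hi = np.searchsorted(t, t + max_lag, side="right")
    for i in range(len(t)):
        lags = t[i + 1 : hi[i]] - t[i]
        lags = lags[lags > 0]
        total += lags.sum()
        count += len(lags)
    if count == 0:
        raise ValueError(f"no spike pairs within {max_lag_ms} ms")
    return 1000.0 * total / count
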