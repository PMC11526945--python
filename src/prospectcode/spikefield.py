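"""Spike-field coupling (pairwise phase consistency) and CA3-CA1 WPLI.

PPC averages cos(phase differences) over all pairs of spikes drawn from
*different* trials, which removes the sample-size bias of the resultant
length: for M trials with per-trial spike phases, with N_m spikes in trial
m,

    PPC = 1/(M(M-1)) * sum_{m != l} [ sum_k sum_j cos(phi_km - phi_jl) ] / (N_m N_l)

PPC is 1 when every spike shares one phase, ~0 for uniform phases, and
negative for anti-phasic modulation. The double sum is evaluated through
per-trial resultant vectors, which is algebraically identical to the pair
sum but O(total spikes).

WPLI is |E[Im X]| / E[|Im X|] over Welch windows of the CA3-CA1 cross
spectrum; it discounts zero-lag (volume-conducted) synchrony.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .config import PipelineConfig
from .lfp import bandpass, hilbert_phase


@dataclass
class PpcResult:
    unit_id: int
    band: str
    epoch: str
    ppc: float
    n_spikes: int
    n_trials: int
    included: bool


@dataclass
class WpliResult:
    frequencies: np.ndarray
    wpli: np.ndarray          # NaN where Im(X) vanishes (zero-lag synchrony)
    window: int
    n_windows: int


def instantaneous_phase(
    lfp: np.ndarray,
    band: tuple[float, float],
    rate: float,
    notch40: bool = False,
    cfg: PipelineConfig | None = None,
) -> np.ndarray:
    """Hilbert phase of the band-filtered LFP, radians in (-pi, pi].

    With ``notch40`` a 40 Hz, 1 Hz-wide notch is applied first to remove
    stimulus-entrained oscillations.
    """
    cfg = cfg or PipelineConfig()
    x = np.asarray(lfp, dtype=float)
    if notch40:
        f0, bw = cfg.notch_freq_hz, cfg.notch_bandwidth_hz
        if band[0] >= f0 - bw / 2 and band[1] <= f0 + bw / 2:
            raise ValueError("band lies entirely inside the notch")
        b, a = signal.iirnotch(f0, f0 / bw, fs=rate)
        x = signal.filtfilt(b, a, x)
    return hilbert_phase(bandpass(x, band, rate))


def spike_phases(
    spike_times: np.ndarray, phase: np.ndarray, rate: float
) -> np.ndarray:
    """Phase at each spike by nearest-sample lookup."""
    idx = np.clip(np.round(np.asarray(spike_times) * rate).astype(int), 0, len(phase) - 1)
    return phase[idx]


def compute_ppc(
    spike_times: np.ndarray,
    phase: np.ndarray,
    rate: float,
    trial_intervals: list[tuple[float, float]],
    cfg: PipelineConfig | None = None,
    unit_id: int = -1,
    band: str = "",
    epoch: str = "",
) -> PpcResult:
    """Pairwise phase consistency of one unit over the given trials.

    Trials without spikes are dropped. Units with <= 100 spikes in total or
    spikes in fewer than 5 trials are flagged not included (ppc still
    returned when computable with >= 2 spiking trials).
    """
    cfg = cfg or PipelineConfig()
    st = np.asarray(spike_times, dtype=float)
    phases_by_trial = []
    for a, b in trial_intervals:
        sel = st[(st >= a) & (st < b)]
        if len(sel):
            phases_by_trial.append(spike_phases(sel, phase, rate))
    n_trials = len(phases_by_trial)
    n_spikes = int(sum(len(p) for p in phases_by_trial))
    included = n_spikes > cfg.ppc_min_spikes and n_trials >= cfg.ppc_min_trials
    ppc = ppc_from_phases(phases_by_trial) if n_trials >= 2 else np.nan
    return PpcResult(
        unit_id=unit_id,
        band=band,
        epoch=epoch,
        ppc=ppc,
        n_spikes=n_spikes,
        n_trials=n_trials,
        included=included,
    )


def ppc_from_phases(phases_by_trial: list[np.ndarray]) -> float:
    """Cross-trial pair average of cos(phase difference).

    Uses per-trial mean resultant vectors u_m: the ordered-pair double sum
    equals |sum u_m|^2 - sum |u_m|^2, divided by M(M-1).
    """
    m = len(phases_by_trial)
    if m < 2:
        raise ValueError("PPC needs at least two trials with spikes")
    u = np.array([np.exp(1j * np.asarray(p)).mean() for p in phases_by_trial])
    total = np.abs(u.sum()) ** 2 - np.sum(np.abs(u) ** 2)
    return float(total.real / (m * (m - 1)))


def ppc_trials_for_epoch(
    epoch: str,
    trials=None,
    flicker_span: tuple[float, float] | None = None,
) -> list[tuple[float, float]]:
    """Trial intervals for PPC: VR half-laps or 1-minute flicker blocks.

    VR trials run from the end of one reward zone through the next reward
    zone, which is exactly the behavior module's half-lap segmentation.
    Flicker trials are consecutive whole 60 s blocks; a final partial
    minute is dropped.
    """
    if epoch == "VR":
        if trials is None:
            raise ValueError("VR epoch requires segmented trials")
        return [(t.start_s, t.end_s) for t in trials]
    if epoch == "flicker":
        if flicker_span is None:
            raise ValueError("flicker epoch requires its time span")
        a, b = flicker_span
        n = int((b - a) // 60.0)
        return [(a + 60.0 * k, a + 60.0 * (k + 1)) for k in range(n)]
    raise ValueError(f"unknown epoch {epoch!r}")


def compute_wpli(
    lfp_ca3: np.ndarray,
    lfp_ca1: np.ndarray,
    rate: float,
    cfg: PipelineConfig | None = None,
) -> WpliResult:
    """Weighted phase-lag index per frequency bin.

    Cross-spectra are taken over non-overlapping Hamming windows of 1024
    samples (NFFT = 1024). Frequencies where E[|Im X|] is numerically zero
    (pure zero-lag coupling) are reported as NaN: WPLI is undefined there.
    """
    cfg = cfg or PipelineConfig()
    x = np.asarray(lfp_ca3, dtype=float)
    y = np.asarray(lfp_ca1, dtype=float)
    if len(x) != len(y):
        raise ValueError("channels must have equal length")
    nw = cfg.wpli_window
    n_windows = len(x) // nw
    if n_windows < 2:
        raise ValueError("need at least two full windows")
    win = np.hamming(nw)
    xs = x[: n_windows * nw].reshape(n_windows, nw) * win
    ys = y[: n_windows * nw].reshape(n_windows, nw) * win
    fx = np.fft.rfft(xs, n=nw, axis=1)
    fy = np.fft.rfft(ys, n=nw, axis=1)
    im = np.imag(fx * np.conj(fy))
    num = np.abs(im.mean(axis=0))
    den = np.abs(im).mean(axis=0)
    scale = np.abs(fx * np.conj(fy)).mean(axis=0)  # reference magnitude per bin
    with np.errstate(invalid="ignore", divide="ignore"):
        wpli = num / den
    wpli[den <= 1e-12 * np.maximum(scale, 1e-300)] = np.nan
    freqs = np.fft.rfftfreq(nw, d=1.0 / rate)
    return WpliResult(frequencies=freqs, wpli=wpli, window=nw, n_windows=n_windows)
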