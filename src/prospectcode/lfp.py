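"""LFP preprocessing, band filtering, brain-state and ripple detection.

Band filters are linear-phase FIR equiripple designs applied with zero net
phase (symmetric kernel, centered convolution), so detected event times are
unbiased. Narrow low-frequency bands are filtered at a decimated rate and
resampled back, which keeps the equiripple design well conditioned while
meeting >= 40 dB attenuation one octave outside each band.

Theta vs non-theta segmentation uses the theta/(delta+beta) envelope ratio:
theta periods require the ratio to exceed mean + 2 SD for at least 2 s,
non-theta periods require it below 1.1 for at least 2 s. Sharp-wave ripples
are threshold crossings of the 150-250 Hz envelope (3 SD, >= 20 ms) with a
100-250 / 250-400 Hz power-ratio check and an amplitude artifact exclusion.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
from scipy import signal

from .config import DELTA_BAND, BETA_BAND, PipelineConfig, RIPPLE_BAND, THETA_BAND
from .session import LfpChannelSet, StateIntervals, SwrEvent

@lru_cache(maxsize=32)
def _design_fir(lo: float, hi: float, rate: float) -> tuple[np.ndarray, int]:
    """Equiripple bandpass taps and the decimation factor they apply at.

    Both transition bands use the same width (0.38*lo), which keeps the
    Parks-McClellan exchange well conditioned (unequal transitions dump
    excess ripple into the wider one); stop edges then sit inside one
    octave of the band so the one-octave attenuation target is met.
    Designs are validated on a dense grid and fall back to a
    Hamming-windowed FIR if the equiripple solution misbehaves.
    """
    tw = 0.38 * lo
    stop_hi = hi + tw
    # filter at a decimated rate when the band allows it
    decim = max(1, int(rate // max(5.0 * hi, 2.5 * stop_hi)))
    fsd = rate / decim
    wanted = int(np.ceil(3.3 * fsd / tw)) | 1
    numtaps = int(np.clip(wanted, 51, 501))
    bands = [0.0, lo - tw, lo, hi, min(stop_hi, 0.98 * fsd / 2), fsd / 2]
    if wanted > 501:
        # under-resolved equiripple problem (very wide band at full rate):
        # a windowed design keeps an exact spectral null at DC
        taps = signal.firwin(
            numtaps, [lo, min(hi, 0.97 * fsd / 2)], pass_zero=False, window="hamming", fs=fsd
        )
        return taps, decim
    taps = signal.remez(numtaps, bands, [0, 1, 0], fs=fsd)
    if not _design_ok(taps, fsd):
        taps = signal.firwin(
            numtaps, [lo - tw / 2, hi + tw / 2], pass_zero=False, window="hamming", fs=fsd
        )
    return taps, decim


def _design_ok(taps: np.ndarray, fsd: float) -> bool:
    w, h = signal.freqz(taps, worN=1 << 16, fs=fsd)
    return bool(np.abs(h).max() <= 1.05)


def bandpass(x: np.ndarray, band: tuple[float, float], rate: float) -> np.ndarray:
    """Zero-phase FIR equiripple bandpass of one series."""
    lo, hi = band
    if not (0 < lo < hi < rate / 2):
        raise ValueError(f"band {band} invalid for rate {rate}")
    x = np.asarray(x, dtype=float)
    x = x - x.mean()  # exact DC removal; the stopband only attenuates it
    taps, decim = _design_fir(float(lo), float(hi), float(rate))
    if decim > 1:
        xd = signal.resample_poly(x, 1, decim)
        yd = signal.fftconvolve(xd, taps, mode="same")
        y = signal.resample_poly(yd, decim, 1)
        y = y[: len(x)]
        if len(y) < len(x):
            y = np.pad(y, (0, len(x) - len(y)))
        return y
    return signal.fftconvolve(x, taps, mode="same")


def envelope(x: np.ndarray, rate: float | None = None, smooth_s: float = 0.0) -> np.ndarray:
    """Hilbert magnitude, optionally smoothed with a moving average."""
    env = np.abs(signal.hilbert(x, N=_fast_len(len(x))))[: len(x)]
    if smooth_s and rate:
        w = max(1, int(round(smooth_s * rate)))
        env = np.convolve(env, np.ones(w) / w, mode="same")
    return env


def hilbert_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase in (-pi, pi]; zero at local maxima of x."""
    return np.angle(signal.hilbert(x, N=_fast_len(len(x))))[: len(x)]


def _fast_len(n: int) -> int:
    from scipy.fft import next_fast_len

    return next_fast_len(n)


def preprocess(raw: np.ndarray, rate: float, cfg: PipelineConfig | None = None) -> LfpChannelSet:
    """Downsample to 2 kHz, bandpass 1-300 Hz, interpolate extreme outliers."""
    cfg = cfg or PipelineConfig()
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    out = []
    for ch in raw:
        sd = ch.std()
        if sd == 0:
            warnings.warn("constant LFP channel; outlier removal skipped")
        else:
            bad = np.abs(ch - ch.mean()) > cfg.outlier_sd * sd
            if bad.any():
                idx = np.arange(len(ch))
                ch = ch.copy()
                ch[bad] = np.interp(idx[bad], idx[~bad], ch[~bad])
        if rate != cfg.lfp_rate:
            up, down = _resample_ratio(cfg.lfp_rate, rate)
            ch = signal.resample_poly(ch, up, down)
        ch = bandpass(ch, cfg.lfp_band, cfg.lfp_rate)
        out.append(ch)
    return LfpChannelSet(samples=np.array(out), rate=cfg.lfp_rate)


def _resample_ratio(target: float, source: float) -> tuple[int, int]:
    from fractions import Fraction

    frac = Fraction(target / source).limit_denominator(1000)
    return frac.numerator, frac.denominator


def theta_delta_beta_ratio(x: np.ndarray, rate: float, cfg: PipelineConfig | None = None) -> np.ndarray:
    """Theta envelope over summed delta + beta envelopes."""
    cfg = cfg or PipelineConfig()
    th = envelope(bandpass(x, THETA_BAND, rate), rate, cfg.envelope_smooth_s)
    de = envelope(bandpass(x, DELTA_BAND, rate), rate, cfg.envelope_smooth_s)
    be = envelope(bandpass(x, BETA_BAND, rate), rate, cfg.envelope_smooth_s)
    ratio = th / (de + be + 1e-12)
    if cfg.ratio_smooth_s > 0:
        # a sample-level "continuously above threshold" rule is meaningless
        # on an envelope ratio that fluctuates at band-noise timescales
        w = max(1, int(round(cfg.ratio_smooth_s * rate)))
        ratio = np.convolve(ratio, np.ones(w) / w, mode="same")
    return ratio


def _runs_above(mask: np.ndarray, min_samples: int) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True at least min_samples long."""
    if not mask.any():
        return []
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[~mask[edges]] + 1)
    stops = list(edges[mask[edges]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask))
    return [(a, b) for a, b in zip(starts, stops) if b - a >= min_samples]


def detect_theta_nontheta(
    lfp: np.ndarray, rate: float, cfg: PipelineConfig | None = None
) -> StateIntervals:
    """Segment one channel into theta and non-theta periods."""
    cfg = cfg or PipelineConfig()
    ratio = theta_delta_beta_ratio(np.asarray(lfp, dtype=float), rate, cfg)
    thr = ratio.mean() + cfg.theta_ratio_sd * ratio.std()
    theta = [
        (a / rate, b / rate)
        for a, b in _runs_above(ratio > thr, int(cfg.theta_min_duration_s * rate))
    ]
    nontheta = [
        (a / rate, b / rate)
        for a, b in _runs_above(
            ratio < cfg.nontheta_ratio_max, int(cfg.nontheta_min_duration_s * rate)
        )
    ]
    if cfg.ratio_baseline == "nontheta" and nontheta:
        base = np.concatenate(
            [ratio[int(a * rate) : int(b * rate)] for a, b in nontheta]
        )
        thr = base.mean() + cfg.theta_ratio_sd * base.std()
        theta = [
            (a / rate, b / rate)
            for a, b in _runs_above(ratio > thr, int(cfg.theta_min_duration_s * rate))
        ]
    return StateIntervals(theta_periods=theta, nontheta_periods=nontheta)


def _band_power(seg: np.ndarray, rate: float, band: tuple[float, float]) -> float:
    freqs, psd = signal.periodogram(seg, fs=rate)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[sel], freqs[sel])) if sel.any() else 0.0


def detect_swr(
    lfp: np.ndarray, rate: float, cfg: PipelineConfig | None = None
) -> list[SwrEvent]:
    """Detect sharp-wave ripple events on the pyramidal-layer channel."""
    cfg = cfg or PipelineConfig()
    x = np.asarray(lfp, dtype=float)
    ripple = bandpass(x, RIPPLE_BAND, rate)
    env = envelope(ripple, rate, cfg.envelope_smooth_s)
    thr = env.mean() + cfg.swr_envelope_sd * env.std()
    runs = _runs_above(env > thr, 1)
    # merge neighbours closer than the merge gap, then apply duration rule
    merged: list[list[int]] = []
    gap = cfg.swr_merge_gap_ms / 1000.0 * rate
    for a, b in runs:
        if merged and a - merged[-1][1] < gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    min_len = cfg.swr_min_duration_ms / 1000.0 * rate
    events = []
    for a, b in merged:
        if b - a < min_len:
            continue
        # analysis segment padded for spectral estimates on short events
        pad = int(0.05 * rate)
        seg = x[max(0, a - pad) : min(len(x), b + pad)]
        p_in = _band_power(seg, rate, (100.0, 250.0))
        p_out = _band_power(seg, rate, (250.0, 400.0))
        ratio = p_in / p_out if p_out > 0 else np.inf
        if ratio < cfg.swr_power_ratio_min:
            continue
        if np.max(np.abs(x[a:b])) > cfg.swr_amplitude_limit_uv:
            continue
        events.append(
            SwrEvent(
                start_s=a / rate,
                end_s=b / rate,
                peak_envelope=float(env[a:b].max()),
                power_ratio=float(ratio),
            )
        )
    return events


def select_pyramidal_channel(lfp: LfpChannelSet) -> int:
    """Channel with the largest mean ripple-band power; ties to lowest id."""
    power = [
        float(np.mean(bandpass(ch, RIPPLE_BAND, lfp.rate) ** 2)) for ch in lfp.samples
    ]
    order = np.lexsort((lfp.channel_ids, -np.round(power, 12)))
    return int(np.asarray(lfp.channel_ids)[order[0]])


def swr_summary(events: list[SwrEvent], nontheta_periods: list[tuple[float, float]]) -> dict:
    """Duration, abundance (events per non-theta second) and size stats."""
    nontheta_time = float(sum(b - a for a, b in nontheta_periods))
    durations = np.array([e.duration_ms for e in events])
    sizes = np.array([e.peak_envelope for e in events])
    return {
        "n_events": len(events),
        "duration_ms_mean": float(durations.mean()) if len(events) else np.nan,
        "size_mean": float(sizes.mean()) if len(events) else np.nan,
        "nontheta_time_s": nontheta_time,
        "abundance_per_s": len(events) / nontheta_time if nontheta_time > 0 else np.nan,
        "abundance_defined": nontheta_time > 0,
    }
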