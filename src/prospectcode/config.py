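"""Pipeline configuration: every analysis threshold and band in one place.

Defaults reproduce the study's printed parameter values; any override is
recorded in the run manifest by the orchestration layer.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

# Frequency bands (Hz). The 4-12 Hz theta band drives state detection and
# theta-cycle extraction; the narrower 6-10 Hz band is used for theta PPC.
DELTA_BAND = (1.0, 4.0)
THETA_BAND = (4.0, 12.0)
THETA_PPC_BAND = (6.0, 10.0)
BETA_BAND = (12.0, 30.0)
SLOW_GAMMA_BAND = (25.0, 55.0)
MEDIUM_GAMMA_BAND = (60.0, 100.0)
RIPPLE_BAND = (150.0, 250.0)

PPC_BANDS = {
    "theta": THETA_PPC_BAND,
    "slow_gamma": SLOW_GAMMA_BAND,
    "medium_gamma": MEDIUM_GAMMA_BAND,
}


@dataclass
class PipelineConfig:
    # --- LFP preprocessing and state detection
    lfp_rate: float = 2000.0           # Hz after downsampling
    lfp_band: tuple = (1.0, 300.0)     # broadband LFP range
    outlier_sd: float = 15.0           # raw-signal outlier rejection
    theta_ratio_sd: float = 2.0        # theta period: ratio > mean + 2 SD
    theta_min_duration_s: float = 2.0
    nontheta_ratio_max: float = 1.1    # non-theta: ratio below this
    nontheta_min_duration_s: float = 2.0
    ratio_baseline: str = "session"    # or "nontheta"
    envelope_smooth_s: float = 0.0     # Hilbert envelope smoothing, off by default
    ratio_smooth_s: float = 1.0        # theta-deltabeta ratio moving average

    # --- SWR detection
    swr_envelope_sd: float = 3.0
    swr_min_duration_ms: float = 20.0
    swr_merge_gap_ms: float = 10.0
    swr_power_ratio_min: float = 4.0   # 100-250 Hz over 250-400 Hz
    swr_amplitude_limit_uv: float = 1500.0  # printed as mV; treated as uV

    # --- unit inclusion and classification
    max_refractory_violation: float = 0.008
    min_snr: float = 1.0
    pyramidal_min_width_ms: float = 0.5
    pyramidal_max_acg_moment_ms: float = 4.5
    acg_max_lag_ms: float = 50.0

    # --- spike-field coupling
    ppc_min_spikes: int = 100          # strictly more than this many spikes
    ppc_min_trials: int = 5
    notch_freq_hz: float = 40.0
    notch_bandwidth_hz: float = 1.0
    wpli_window: int = 1024            # Hamming, non-overlapping, NFFT = 1024

    # --- place fields
    movement_speed_min: float = 1.0    # deg/s
    ratemap_smooth_sd_bins: float = 2.0
    min_occupancy_s: float = 0.1       # bins below this excluded from SI
    n_shuffles: int = 500
    shuffle_min_shift_s: float = 20.0
    shuffle_mode: str = "per_spike"     # or "whole_train"
    place_min_mean_rate: float = 0.2   # Hz
    place_max_mean_rate: float = 10.0
    place_min_peak_rate: float = 1.0

    # --- Bayesian decoding
    decode_tau_s: float = 0.2
    decode_min_spikes: int = 2
    n_folds: int = 5
    rate_floor_hz: float = 0.01
    qc_min_normalized_prob: float = 1.2

    # --- theta sequences
    theta_window_s: float = 0.4        # centered on each trough
    theta_bin_s: float = 0.02
    quadrant_time_ms: float = 80.0
    quadrant_pos_deg: float = 45.0
    sequence_shuffles: int = 500
    far_zone_span_deg: tuple = (162.0, 198.0)

    # --- SWR decoding
    swr_window_s: float = 0.25
    swr_bin_s: float = 0.025
    swr_min_bin_spikes: int = 2        # strictly more than 1 spike
    swr_local_exclusion_deg: float = 9.0
    swr_far_window_deg: float = 63.0
    prospective_swr_threshold: float = 0.1

    # --- misc
    post_reward_n_zones: int = 2
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("lfp_band", "far_zone_span_deg"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def overrides(self) -> dict:
        """Non-default fields, for manifest logging."""
        ref = PipelineConfig()
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if getattr(self, f.name) != getattr(ref, f.name)
        }
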