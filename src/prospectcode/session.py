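"""Containers binding behavior, LFP, spikes and detected states on one clock.

All times are seconds from session start. Positions are degrees on the
annular track in [0, 360). File I/O uses plain-text CSV for behavior and
spikes, flat binary float32 plus a JSON sidecar for LFP, and JSON for
ground truth and manifests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import TrackGeometry


@dataclass
class BehaviorTrace:
    """Timestamped position/speed samples plus lick and reward event times."""

    time: np.ndarray
    position: np.ndarray
    speed: np.ndarray
    licks: np.ndarray
    rewards: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.licks = np.asarray(self.licks, dtype=float)
        self.rewards = np.asarray(self.rewards, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("behavior time must be strictly increasing")
        if np.any((self.position < 0) | (self.position >= 360)):
            raise ValueError("position must lie in [0, 360)")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))

    def position_at(self, t) -> np.ndarray:
        """Circularly correct position interpolation at arbitrary times."""
        unwrapped = np.unwrap(np.deg2rad(self.position))
        interp = np.interp(t, self.time, unwrapped)
        return np.mod(np.rad2deg(interp), 360.0)

    def speed_at(self, t) -> np.ndarray:
        return np.interp(t, self.time, self.speed)

    def to_frame(self) -> pd.DataFrame:
        lick = np.zeros(len(self.time), dtype=int)
        rew = np.zeros(len(self.time), dtype=int)
        lick[np.searchsorted(self.time, self.licks).clip(0, len(self.time) - 1)] = 1
        rew[np.searchsorted(self.time, self.rewards).clip(0, len(self.time) - 1)] = 1
        return pd.DataFrame(
            {
                "time_s": self.time,
                "position_deg": self.position,
                "speed_deg_s": self.speed,
                "lick": lick,
                "reward": rew,
            }
        )


@dataclass
class SpikeUnit:
    """One sorted unit: spike times plus quality and classification metadata."""

    unit_id: int
    region: str
    spike_times: np.ndarray
    spike_width_ms: float = np.nan
    acg_first_moment_ms: float = np.nan
    snr: float = np.nan
    refractory_violation_frac: float = np.nan
    cell_type: str = "unclassified"

    def __post_init__(self):
        self.spike_times = np.sort(np.asarray(self.spike_times, dtype=float))
        if self.region not in ("CA1", "CA3"):
            raise ValueError(f"region must be CA1 or CA3, got {self.region!r}")

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass
class LfpChannelSet:
    """Multi-channel LFP: samples (n_channels, n_samples) at a common rate."""

    samples: np.ndarray
    rate: float
    channel_ids: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not self.channel_ids:
            self.channel_ids = list(range(self.samples.shape[0]))
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValueError("channel_ids length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def channel(self, channel_id: int) -> np.ndarray:
        return self.samples[self.channel_ids.index(channel_id)]


@dataclass
class SwrEvent:
    """One detected sharp-wave ripple."""

    start_s: float
    end_s: float
    peak_envelope: float
    power_ratio: float

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * (self.end_s - self.start_s)


@dataclass
class StateIntervals:
    """Theta / non-theta periods and SWR events detected from the LFP."""

    theta_periods: list[tuple[float, float]] = field(default_factory=list)
    nontheta_periods: list[tuple[float, float]] = field(default_factory=list)
    swr_events: list[SwrEvent] = field(default_factory=list)

    def in_theta(self, t) -> np.ndarray:
        return _in_intervals(t, self.theta_periods)

    def in_nontheta(self, t) -> np.ndarray:
        return _in_intervals(t, self.nontheta_periods)


def _in_intervals(t, intervals) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    mask = np.zeros(t.shape, dtype=bool)
    for a, b in intervals:
        mask |= (t >= a) & (t <= b)
    return mask


@dataclass
class Session:
    """One recording session on a common clock."""

    behavior: BehaviorTrace
    lfp: LfpChannelSet
    units: list[SpikeUnit]
    geometry: TrackGeometry = field(default_factory=TrackGeometry)
    states: StateIntervals | None = None
    ground_truth: dict | None = None

    @property
    def duration(self) -> float:
        return max(self.behavior.time[-1], self.lfp.n_samples / self.lfp.rate)

    def units_by_type(self, cell_type: str, region: str | None = None) -> list[SpikeUnit]:
        out = [u for u in self.units if u.cell_type == cell_type]
        if region is not None:
            out = [u for u in out if u.region == region]
        return out


# ---------------------------------------------------------------------------
# Disk I/O


def save_session(session: Session, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.behavior.to_frame().to_csv(out / "behavior.csv", index=False)

    session.lfp.samples.astype(np.float32).tofile(out / "lfp.bin")
    (out / "lfp.json").write_text(
        json.dumps(
            {
                "rate": session.lfp.rate,
                "n_channels": session.lfp.n_channels,
                "channel_ids": session.lfp.channel_ids,
                "dtype": "float32",
            }
        )
    )

    rows = []
    meta = []
    for u in session.units:
        rows.extend(
            {"unit_id": u.unit_id, "region": u.region, "time_s": t} for t in u.spike_times
        )
        meta.append(
            {
                "unit_id": u.unit_id,
                "region": u.region,
                "spike_width_ms": u.spike_width_ms,
                "acg_first_moment_ms": u.acg_first_moment_ms,
                "snr": u.snr,
                "refractory_violation_frac": u.refractory_violation_frac,
                "cell_type": u.cell_type,
            }
        )
    pd.DataFrame(rows, columns=["unit_id", "region", "time_s"]).to_csv(
        out / "spikes.csv", index=False
    )
    pd.DataFrame(meta).to_csv(out / "units.csv", index=False)

    if session.ground_truth is not None:
        (out / "ground_truth.json").write_text(
            json.dumps(session.ground_truth, default=_json_default, indent=1)
        )


def load_session(in_dir, geometry: TrackGeometry | None = None) -> Session:
    src = Path(in_dir)
    beh = pd.read_csv(src / "behavior.csv")
    behavior = BehaviorTrace(
        time=beh["time_s"].to_numpy(),
        position=beh["position_deg"].to_numpy(),
        speed=beh["speed_deg_s"].to_numpy(),
        licks=beh.loc[beh["lick"] == 1, "time_s"].to_numpy(),
        rewards=beh.loc[beh["reward"] == 1, "time_s"].to_numpy(),
    )

    meta = json.loads((src / "lfp.json").read_text())
    raw = np.fromfile(src / "lfp.bin", dtype=np.float32)
    lfp = LfpChannelSet(
        samples=raw.reshape(meta["n_channels"], -1),
        rate=meta["rate"],
        channel_ids=list(meta["channel_ids"]),
    )

    spikes = pd.read_csv(src / "spikes.csv")
    units_meta = pd.read_csv(src / "units.csv")
    units = []
    for _, row in units_meta.iterrows():
        st = spikes.loc[spikes["unit_id"] == row["unit_id"], "time_s"].to_numpy()
        units.append(
            SpikeUnit(
                unit_id=int(row["unit_id"]),
                region=row["region"],
                spike_times=st,
                spike_width_ms=row["spike_width_ms"],
                acg_first_moment_ms=row["acg_first_moment_ms"],
                snr=row["snr"],
                refractory_violation_frac=row["refractory_violation_frac"],
                cell_type=row.get("cell_type", "unclassified"),
            )
        )

    gt_path = src / "ground_truth.json"
    ground_truth = json.loads(gt_path.read_text()) if gt_path.exists() else None
    return Session(
        behavior=behavior,
        lfp=lfp,
        units=units,
        geometry=geometry or TrackGeometry(),
        ground_truth=ground_truth,
    )


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
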