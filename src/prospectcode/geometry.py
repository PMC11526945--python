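"""Track geometry and circular-position helpers.

The task environment is an annular track of 360 degrees divided into 20
zones of 18 degrees each, with two reward zones located 180 degrees apart.
Because behavior is symmetric across the two half-laps, most analyses fold
the track onto a 180-degree "distance to reward" axis where 0 is the exit
of a reward zone and 180 is the end of the next reward zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FULL_TRACK_DEG = 360.0
ZONE_WIDTH_DEG = 18.0
FOLDED_TRACK_DEG = 180.0


def wrap_angle(theta, period: float = FULL_TRACK_DEG):
    """Wrap angles into [0, period)."""
    return np.mod(theta, period)


def circ_diff(a, b, period: float = FULL_TRACK_DEG):
    """Signed circular difference a - b in (-period/2, period/2]."""
    d = np.mod(np.asarray(a, dtype=float) - b, period)
    return np.where(d > period / 2, d - period, d)


def circ_dist(a, b, period: float = FULL_TRACK_DEG):
    """Unsigned circular distance between a and b."""
    return np.abs(circ_diff(a, b, period))


@dataclass(frozen=True)
class BinGeometry:
    """Uniform angular binning of a (possibly folded) track.

    Two standard geometries are used: the full track (360 deg, 2-deg bins)
    and the folded distance-to-reward axis (180 deg, 3-deg bins).
    """

    span_deg: float
    bin_width_deg: float

    @property
    def n_bins(self) -> int:
        return int(round(self.span_deg / self.bin_width_deg))

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.span_deg, self.n_bins + 1)

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_deg

    def bin_index(self, pos) -> np.ndarray:
        idx = np.floor(np.mod(pos, self.span_deg) / self.bin_width_deg)
        return np.clip(idx.astype(int), 0, self.n_bins - 1)


FULL_TRACK_BINS = BinGeometry(360.0, 2.0)
FOLDED_BINS = BinGeometry(180.0, 3.0)


@dataclass(frozen=True)
class TrackGeometry:
    """Annular track with evenly spaced zones and two opposite reward zones."""

    n_zones: int = 20
    zone_width_deg: float = ZONE_WIDTH_DEG
    reward_zone_indices: tuple[int, int] = (4, 14)

    def __post_init__(self):
        if self.n_zones * self.zone_width_deg != FULL_TRACK_DEG:
            raise ValueError("zones must tile the 360-degree track")
        i, j = self.reward_zone_indices
        sep = abs(j - i) * self.zone_width_deg
        if sep != FULL_TRACK_DEG / 2:
            raise ValueError("reward zones must be 180 degrees apart")

    @property
    def reward_zone_spans(self) -> list[tuple[float, float]]:
        w = self.zone_width_deg
        return [(i * w, (i + 1) * w) for i in self.reward_zone_indices]

    @property
    def anticipatory_zone_spans(self) -> list[tuple[float, float]]:
        """The 18-degree zone immediately preceding each reward zone."""
        w = self.zone_width_deg
        out = []
        for i in self.reward_zone_indices:
            j = (i - 1) % self.n_zones
            out.append((j * w, (j + 1) * w))
        return out

    @property
    def reward_zone_ends(self) -> list[float]:
        return [span[1] % FULL_TRACK_DEG for span in self.reward_zone_spans]

    def fold(self, position_deg):
        """Map absolute position to distance travelled since reward-zone exit.

        The folded axis runs from 0 (exit of a reward zone) to 180 (end of
        the next reward zone); the anticipatory zone occupies [144, 162)
        and the reward zone [162, 180).
        """
        origin = self.reward_zone_ends[0]
        return np.mod(np.asarray(position_deg, dtype=float) - origin, FOLDED_TRACK_DEG)

    def in_reward_zone(self, position_deg) -> np.ndarray:
        return self.fold(position_deg) >= FOLDED_TRACK_DEG - self.zone_width_deg

    def in_anticipatory_zone(self, position_deg) -> np.ndarray:
        f = self.fold(position_deg)
        return (f >= FOLDED_TRACK_DEG - 2 * self.zone_width_deg) & (
            f < FOLDED_TRACK_DEG - self.zone_width_deg
        )

    def in_reward_related_zones(self, position_deg) -> np.ndarray:
        """Anticipatory zone plus reward zone."""
        return self.fold(position_deg) >= FOLDED_TRACK_DEG - 2 * self.zone_width_deg

    def in_post_reward_zones(self, position_deg, n_zones: int = 2) -> np.ndarray:
        """The first ``n_zones`` zones after reward-zone exit."""
        return self.fold(position_deg) < n_zones * self.zone_width_deg

    def control_zone_span_folded(self) -> tuple[float, float]:
        """Control zone half the distance to the next reward zone (folded)."""
        center = FOLDED_TRACK_DEG - self.zone_width_deg / 2 - FOLDED_TRACK_DEG / 2
        half = self.zone_width_deg / 2
        return (center - half, center + half)
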