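"""Corridor geometry, spatial binning and experimental-phase conventions.

The virtual corridor is a 400 cm linear track with four 40 cm reward zones
(RZs). All spatial analyses share one binning convention: 0-based, half-open
bins ``[k*bin_size, (k+1)*bin_size)``. This module is the single source of
truth for those coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CorridorConfig", "phase_of_day", "PHASES"]

PHASES = ("healthy", "early_post", "late_post")


@dataclass(frozen=True)
class CorridorConfig:
    """Geometry of the virtual track, binning and reward zones.

    Parameters
    ----------
    length_cm
        Total corridor length (default 400 cm).
    bin_size_cm
        Width of the spatial bins used for neural activity maps (default 5 cm,
        i.e. 80 bins).
    lick_bin_count
        Number of (finer) bins used for the behavioural lick histogram
        (default 120).
    rz_centers_cm
        Centres of the reward zones (default 30, 137, 243 and 350 cm).
    rz_width_cm
        Width of each reward zone (default 40 cm).
    frame_rate_hz
        Imaging / behaviour sampling rate (default 30 Hz).
    """

    length_cm: float = 400.0
    bin_size_cm: float = 5.0
    lick_bin_count: int = 120
    rz_centers_cm: tuple = (30.0, 137.0, 243.0, 350.0)
    rz_width_cm: float = 40.0
    frame_rate_hz: float = 30.0

    def __post_init__(self):
        if self.length_cm <= 0 or self.bin_size_cm <= 0:
            raise ValueError("length_cm and bin_size_cm must be positive")
        n = self.length_cm / self.bin_size_cm
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"length_cm / bin_size_cm = {n} is not an integer bin count"
            )
        if self.lick_bin_count < 1:
            raise ValueError("lick_bin_count must be a positive integer")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        for c in self.rz_centers_cm:
            lo, hi = c - self.rz_width_cm / 2, c + self.rz_width_cm / 2
            if lo < 0 or hi > self.length_cm:
                raise ValueError(
                    f"reward zone centred at {c} cm extends outside the corridor"
                )

    @property
    def n_bins(self) -> int:
        """Number of neural-activity spatial bins (default 80)."""
        return int(round(self.length_cm / self.bin_size_cm))

    @property
    def rz_edges_cm(self) -> list[tuple[float, float]]:
        """(start, end) of each reward zone in cm."""
        h = self.rz_width_cm / 2
        return [(c - h, c + h) for c in self.rz_centers_cm]

    def bin_of(self, position_cm):
        """Map positions (cm) to 0-based half-open bin indices.

        The corridor end ``position == length_cm`` is clipped into the last
        bin so a frame standing exactly at the wall is not lost.
        """
        idx = np.floor(np.asarray(position_cm) / self.bin_size_cm).astype(int)
        return np.clip(idx, 0, self.n_bins - 1)

    def lick_bin_of(self, position_cm):
        """Map positions (cm) to lick-histogram bin indices (finer grid)."""
        w = self.length_cm / self.lick_bin_count
        idx = np.floor(np.asarray(position_cm) / w).astype(int)
        return np.clip(idx, 0, self.lick_bin_count - 1)

    def in_reward_zone(self, position_cm):
        """Boolean mask: is each position inside any reward zone?"""
        pos = np.asarray(position_cm, dtype=float)
        mask = np.zeros(pos.shape, dtype=bool)
        for lo, hi in self.rz_edges_cm:
            mask |= (pos >= lo) & (pos <= hi)
        return mask

    def rz_bins(self) -> np.ndarray:
        """Indices of neural-activity bins whose centre lies inside an RZ."""
        centers = (np.arange(self.n_bins) + 0.5) * self.bin_size_cm
        return np.nonzero(self.in_reward_zone(centers))[0]

    def distance_to_rz(self, position_cm) -> np.ndarray:
        """Distance (cm) from each position to the nearest RZ edge, 0 inside."""
        pos = np.atleast_1d(np.asarray(position_cm, dtype=float))
        d = np.full(pos.shape, np.inf)
        for lo, hi in self.rz_edges_cm:
            inside = (pos >= lo) & (pos <= hi)
            dist = np.where(inside, 0.0, np.minimum(np.abs(pos - lo), np.abs(pos - hi)))
            d = np.minimum(d, dist)
        return d


def phase_of_day(day: int) -> str:
    """Assign an experimental phase to a session day (relative to injection).

    Day 0 (the injection day) still counts as healthy: the last baseline
    session is imaged on the same day, before the injection. Days past the
    nominal 28-day endpoint remain ``late_post`` so the function stays total.
    """
    if day <= 0:
        return "healthy"
    if day <= 7:
        return "early_post"
    return "late_post"
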