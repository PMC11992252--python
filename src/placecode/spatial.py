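"""ΔF/F detrending and velocity-filtered spatial activity maps.

Fluorescence traces are detrended as ΔF/F = (F − F0)/(B0 + F0), where the
rolling baselines F0 and B0 sit at the percentile of the distribution mode,
estimated per 1000-frame window. Activity is then binned along the corridor
(5 cm bins, running-velocity filter at 5 cm/s) into per-trial and trial-mean
spatial activity maps, which are smoothed with a Gaussian kernel (σ = 5 cm).
These maps are the substrate of place-field detection, stability scoring,
population-vector correlation and the Bayesian decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .corridor import CorridorConfig
from .session import SessionData

__all__ = [
    "FluorescenceComponents",
    "SpatialActivityMap",
    "rolling_mode_percentile",
    "rolling_percentile_baseline",
    "compute_dff",
    "bin_activity",
    "smooth_map",
]


@dataclass
class FluorescenceComponents:
    """Raw trace, rolling baselines and the resulting ΔF/F of one ROI.

    F is the background-corrected ROI trace, F0 its rolling baseline, B0 the
    rolling baseline of the background trace; dff = (F − F0)/(B0 + F0).
    """

    F: np.ndarray
    F0: np.ndarray
    B0: np.ndarray

    @property
    def dff(self) -> np.ndarray:
        return compute_dff(self.F, self.F0, self.B0)

    @classmethod
    def from_traces(cls, F: np.ndarray, background: np.ndarray,
                    window_frames: int = 1000) -> "FluorescenceComponents":
        """Build baselines at the mode percentile of the ROI trace."""
        pct = rolling_mode_percentile(F, window_frames)
        return cls(F=np.asarray(F, float),
                   F0=rolling_percentile_baseline(F, pct, window_frames),
                   B0=rolling_percentile_baseline(background, pct, window_frames))


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------

def _window_mode(values: np.ndarray) -> float:
    """Mode of a sample located by a Gaussian KDE (Silverman bandwidth)."""
    if np.ptp(values) == 0:
        return float(values[0])
    kde = stats.gaussian_kde(values)   # Silverman's rule by default
    grid = np.linspace(values.min(), values.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def rolling_mode_percentile(trace: np.ndarray, window_frames: int = 1000) -> float:
    """Percentile rank of the distribution mode, median across windows.

    For each sliding window (stride = window/2) the mode of the fluorescence
    values is located by kernel density estimation and its percentile rank
    within that window computed; the median across windows is returned. For
    a symmetric unimodal trace this sits near 50; sparse positive transients
    skew the distribution right and pull the mode's percentile below 50.
    A constant trace returns 50 by convention.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) < window_frames:
        raise ValueError(
            f"trace length {len(trace)} is shorter than the window ({window_frames})")
    if np.ptp(trace) == 0:
        return 50.0
    stride = max(window_frames // 2, 1)
    percentiles = []
    for start in range(0, len(trace) - window_frames + 1, stride):
        w = trace[start:start + window_frames]
        if np.ptp(w) == 0:
            percentiles.append(50.0)
            continue
        mode = _window_mode(w)
        percentiles.append(stats.percentileofscore(w, mode, kind="mean"))
    return float(np.median(percentiles))


def rolling_percentile_baseline(trace: np.ndarray, percentile: float,
                                window_frames: int = 1000) -> np.ndarray:
    """Rolling-window percentile of a trace, linearly interpolated per frame."""
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if n < window_frames:
        return np.full(n, np.percentile(trace, percentile))
    stride = max(window_frames // 2, 1)
    starts = np.arange(0, n - window_frames + 1, stride)
    centers = starts + window_frames // 2
    vals = np.array([np.percentile(trace[s:s + window_frames], percentile)
                     for s in starts])
    return np.interp(np.arange(n), centers, vals)


def compute_dff(F: np.ndarray, F0: np.ndarray, B0: np.ndarray) -> np.ndarray:
    """Detrend a fluorescence trace: ΔF/F = (F − F0) / (B0 + F0).

    F is the background-corrected ROI trace, F0 its rolling baseline, and B0
    the rolling baseline of the background trace. Raises if the denominator
    vanishes anywhere, naming the offending frames.
    """
    F = np.asarray(F, dtype=float)
    F0 = np.asarray(F0, dtype=float)
    B0 = np.asarray(B0, dtype=float)
    if not (F.shape == F0.shape == B0.shape):
        raise ValueError("F, F0 and B0 must have equal length")
    denom = B0 + F0
    bad = np.nonzero(denom == 0)[0]
    if bad.size:
        raise ValueError(f"B0 + F0 is zero at frames {bad[:10].tolist()}"
                         + ("..." if bad.size > 10 else ""))
    return (F - F0) / denom


# ---------------------------------------------------------------------------
# spatial binning
# ---------------------------------------------------------------------------

@dataclass
class SpatialActivityMap:
    """Velocity-filtered, spatially binned activity of one session.

    ``per_trial`` is trials × neurons × bins with NaN marking bins the animal
    never crossed (above threshold) in that trial; ``trial_mean`` averages
    over trials ignoring missing bins; ``smoothed`` / ``smoothed_per_trial``
    apply the Gaussian kernel. ``occupancy_frames`` counts the filtered
    frames per bin over the whole session.
    """

    per_trial: np.ndarray
    trial_mean: np.ndarray
    smoothed: np.ndarray
    smoothed_per_trial: np.ndarray
    occupancy_frames: np.ndarray
    config: CorridorConfig

    @property
    def n_neurons(self) -> int:
        return self.trial_mean.shape[0]

    @property
    def n_bins(self) -> int:
        return self.trial_mean.shape[1]


def bin_activity(session: SessionData, config: CorridorConfig,
                 velocity_threshold: float = 5.0,
                 smooth_sigma_cm: float = 5.0) -> SpatialActivityMap:
    """Build the spatial activity map for every neuron of a session.

    Frames outside trial bounds or with running velocity strictly below the
    threshold (5 cm/s; exactly 5 is kept) are excluded. Each trial's map is
    the mean ΔF/F of the remaining frames per 5 cm bin; the session map is
    the across-trial mean, ignoring bins missing in a given trial. Both the
    trial-mean and the per-trial maps are smoothed independently (the latter
    feed stability and the decoder).
    """
    trial = session.trial_of_frame()
    keep = (trial >= 0) & (session.velocity_cm_s >= velocity_threshold)
    if not keep.any():
        raise ValueError("no frames pass the velocity filter")
    n_bins = config.n_bins
    bins = config.bin_of(session.position_cm)
    n_trials = session.n_trials
    flat = trial[keep] * n_bins + bins[keep]

    counts = np.bincount(flat, minlength=n_trials * n_bins)
    per_trial = np.full((n_trials, session.n_neurons, n_bins), np.nan)
    for j in range(session.n_neurons):
        sums = np.bincount(flat, weights=session.dff[j, keep],
                           minlength=n_trials * n_bins)
        with np.errstate(invalid="ignore"):
            m = (sums / counts).reshape(n_trials, n_bins)
        per_trial[:, j, :] = m

    with np.errstate(invalid="ignore"):
        trial_mean = np.nanmean(per_trial, axis=0)

    smoothed = smooth_map(trial_mean, sigma_cm=smooth_sigma_cm, config=config)
    smoothed_pt = np.stack([
        smooth_map(per_trial[t], sigma_cm=smooth_sigma_cm, config=config)
        for t in range(n_trials)
    ])
    occupancy = np.bincount(bins[keep], minlength=n_bins)
    return SpatialActivityMap(
        per_trial=per_trial, trial_mean=trial_mean, smoothed=smoothed,
        smoothed_per_trial=smoothed_pt, occupancy_frames=occupancy,
        config=config,
    )


def _interp_nan(row: np.ndarray) -> np.ndarray:
    """Linearly interpolate NaN bins from their visited neighbours."""
    out = row.copy()
    nan = np.isnan(out)
    if nan.all() or not nan.any():
        return out
    idx = np.arange(len(out))
    out[nan] = np.interp(idx[nan], idx[~nan], out[~nan])
    return out


def smooth_map(maps: np.ndarray, sigma_cm: float = 5.0,
               config: CorridorConfig | None = None,
               bin_size_cm: float | None = None) -> np.ndarray:
    """Gaussian smoothing along position with reflective boundaries.

    σ is given in cm and converted to bins. The corridor ends are walls, so
    the kernel is mirrored there (mass-conserving). Missing bins are filled
    by linear interpolation from visited neighbours before smoothing and
    re-flagged afterwards, so empty bins never smear zeros into their
    neighbourhood. σ = 0 is the identity.
    """
    maps = np.asarray(maps, dtype=float)
    single = maps.ndim == 1
    rows = np.atleast_2d(maps)
    if rows.shape[1] < 3:
        raise ValueError("smoothing requires at least 3 bins")
    bin_size = bin_size_cm if bin_size_cm is not None else (
        config.bin_size_cm if config is not None else 5.0)
    sigma_bins = sigma_cm / bin_size
    out = np.empty_like(rows)
    for i, row in enumerate(rows):
        nan = np.isnan(row)
        if nan.all():
            out[i] = row
            continue
        filled = _interp_nan(row)
        if sigma_bins > 0:
            filled = gaussian_filter1d(filled, sigma_bins, mode="reflect")
        filled[nan] = np.nan
        out[i] = filled
    return out[0] if single else out
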