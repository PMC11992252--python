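"""Place-field detection, bootstrap significance and stability classification.

A neuron is a place cell in a session when its smoothed spatial activity map
contains at least one candidate field that passes all three criteria —

1. minimum width 15 cm (3 bins at 5 cm),
2. mean ΔF/F inside the field at least 6x the mean outside,
3. significant calcium transients covering at least 20% of the (velocity-
   filtered) time the animal spends inside the field,

— and that field survives a chunk-shuffle bootstrap: the ΔF/F trace is cut
into 50-frame pieces, the pieces permuted 1000 times, detection re-run on
each shuffle, and p_pf is the fraction of shuffles that still produce a
passing field; the cell is a place cell iff p_pf ≤ 0.05. Significant
transients are runs of at least 0.5 s above 3σ, with the noise level σ taken
from the FWHM of the ΔF/F value distribution.

Stability is scored by Pearson correlations of spatial maps: within a session
between trial halves and odd/even trials (Fisher-averaged), and across
sessions 3 days apart within each experimental phase. Place cells above the
network's pre-injection median stability are "stable", the rest "unstable".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .corridor import CorridorConfig
from .session import SessionData
from .spatial import _interp_nan, smooth_map

__all__ = [
    "PlaceField",
    "DetectionContext",
    "noise_sigma_fwhm",
    "significant_transients",
    "candidate_fields",
    "field_criteria",
    "detection_context",
    "detect_place_fields",
    "bootstrap_pvalue",
    "classify_place_cell",
    "within_session_stability",
    "cross_session_stability",
    "classify_stability",
    "fisher_mean",
    "nan_pearson",
]

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))   # FWHM = 2.3548 sigma


@dataclass
class PlaceField:
    """One candidate place field and its criterion outcomes."""

    bin_start: int                # half-open [bin_start, bin_end)
    bin_end: int
    width_cm: float
    in_field_mean: float
    out_field_mean: float
    transient_coverage: float
    passes_width: bool
    passes_ratio: bool
    passes_coverage: bool
    p_pf: float = np.nan

    @property
    def passes(self) -> bool:
        return self.passes_width and self.passes_ratio and self.passes_coverage


# ---------------------------------------------------------------------------
# noise and transients
# ---------------------------------------------------------------------------

def noise_sigma_fwhm(trace: np.ndarray, n_grid: int = 512) -> float:
    """Noise level σ from the FWHM of the ΔF/F value distribution.

    The central peak of the distribution is dominated by baseline noise even
    when sparse transients add a right tail; a KDE locates that peak, and
    σ = FWHM / (2·sqrt(2 ln 2)) converts its full width at half maximum to a
    Gaussian standard deviation. Constant traces return 0 with a warning.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) < 100:
        raise ValueError("need at least 100 frames to estimate the noise level")
    if np.ptp(trace) == 0:
        warnings.warn("constant trace: noise sigma set to 0")
        return 0.0
    kde = stats.gaussian_kde(trace)
    grid = np.linspace(trace.min(), trace.max(), n_grid)
    dens = kde(grid)
    peak = np.argmax(dens)
    half = dens[peak] / 2.0

    def cross(idx_range, reverse):
        for k in idx_range:
            if dens[k] < half:
                # linear interpolation between k and its inward neighbour
                k2 = k + 1 if reverse else k - 1
                frac = (half - dens[k]) / (dens[k2] - dens[k])
                return grid[k] + frac * (grid[k2] - grid[k])
        return grid[idx_range[-1]]

    left = cross(range(peak, -1, -1), reverse=True)
    right = cross(range(peak, n_grid), reverse=False)
    return float((right - left) / GAUSS_FWHM)


def significant_transients(dff: np.ndarray, sigma: float,
                           frame_rate_hz: float = 30.0,
                           min_duration_s: float = 0.5,
                           threshold_sigmas: float = 3.0) -> list[tuple[int, int]]:
    """Maximal runs of frames above 3σ lasting at least 0.5 s.

    Returns half-open (start, end) frame intervals.
    """
    min_len = int(np.ceil(min_duration_s * frame_rate_hz))
    above = np.asarray(dff) > threshold_sigmas * sigma
    return _runs(above, min_len)


def _runs(mask: np.ndarray, min_len: int = 1) -> list[tuple[int, int]]:
    """Half-open (start, end) intervals of maximal True runs of length >= min_len."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, len(m)]
    return [(int(a), int(b)) for a, b in zip(starts, ends) if b - a >= min_len]


def _transient_mask(n_frames: int, intervals) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    for a, b in intervals:
        mask[a:b] = True
    return mask


# ---------------------------------------------------------------------------
# candidate fields and criteria
# ---------------------------------------------------------------------------

def candidate_fields(map_row: np.ndarray) -> list[tuple[int, int]]:
    """Screen a smoothed activity map for putative place fields.

    The baseline is the mean of the lowest quartile of bin values; bins
    strictly above baseline + 25% of (max − baseline) form candidate runs.
    A flat map (max == baseline) yields no candidates.
    """
    row = np.asarray(map_row, dtype=float)
    if np.isnan(row).any():
        raise ValueError("candidate_fields requires an interpolated (NaN-free) map row")
    order = np.sort(row)
    n_low = max(1, int(np.ceil(len(row) * 0.25)))
    baseline = order[:n_low].mean()
    peak = row.max()
    if peak - baseline <= 1e-12 * max(1.0, abs(peak)):   # flat map
        return []
    threshold = baseline + 0.25 * (peak - baseline)
    return _runs(row > threshold)


@dataclass
class DetectionContext:
    """Precomputed session geometry shared by detection and its bootstrap.

    Holding the (trial, bin) assignment of every velocity-filtered frame
    fixed lets each bootstrap shuffle re-run full detection with two
    bincounts instead of rebuilding the session map from scratch.
    """

    keep: np.ndarray          # bool per frame: in-trial and >= velocity threshold
    flat: np.ndarray          # per kept frame: trial * n_bins + bin
    counts: np.ndarray        # frames per (trial, bin) cell
    bins_kept: np.ndarray     # corridor bin per kept frame
    n_trials: int
    n_bins: int
    frame_rate_hz: float
    bin_size_cm: float
    smooth_sigma_cm: float = 5.0


def detection_context(session: SessionData, config: CorridorConfig,
                      velocity_threshold: float = 5.0,
                      smooth_sigma_cm: float = 5.0) -> DetectionContext:
    trial = session.trial_of_frame()
    keep = (trial >= 0) & (session.velocity_cm_s >= velocity_threshold)
    if not keep.any():
        raise ValueError("no frames pass the velocity filter")
    bins = config.bin_of(session.position_cm)
    flat = trial[keep] * config.n_bins + bins[keep]
    counts = np.bincount(flat, minlength=session.n_trials * config.n_bins)
    return DetectionContext(
        keep=keep, flat=flat, counts=counts, bins_kept=bins[keep],
        n_trials=session.n_trials, n_bins=config.n_bins,
        frame_rate_hz=session.frame_rate_hz, bin_size_cm=config.bin_size_cm,
        smooth_sigma_cm=smooth_sigma_cm,
    )


def _trace_to_smoothed_map(trace: np.ndarray, ctx: DetectionContext) -> np.ndarray:
    """Velocity-filtered trial-mean map of one trace, interpolated + smoothed."""
    sums = np.bincount(ctx.flat, weights=trace[ctx.keep],
                       minlength=ctx.n_trials * ctx.n_bins)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN bins stay NaN
        per_trial = (sums / ctx.counts).reshape(ctx.n_trials, ctx.n_bins)
        mean_map = np.nanmean(per_trial, axis=0)
    filled = _interp_nan(mean_map)
    if np.isnan(filled).any():      # session never passed the filter anywhere
        return filled
    return smooth_map(filled, sigma_cm=ctx.smooth_sigma_cm,
                      bin_size_cm=ctx.bin_size_cm)


def field_criteria(run: tuple[int, int], map_row: np.ndarray,
                   transient_mask: np.ndarray, ctx: DetectionContext,
                   min_width_cm: float = 15.0, ratio: float = 6.0,
                   min_coverage: float = 0.20) -> PlaceField:
    """Evaluate the three place-field criteria for one candidate run.

    Criterion 2 compares mean ΔF/F inside vs outside the field on the
    smoothed map; when the outside mean is <= 0 the ratio is undefined and
    the criterion is read as "strong contrast": it passes iff the inside
    mean is positive. Criterion 3 measures what fraction of the velocity-
    filtered frames the animal spent inside the field overlap a significant
    transient.
    """
    a, b = run
    row = np.asarray(map_row, dtype=float)
    in_mean = float(row[a:b].mean())
    outside = np.r_[row[:a], row[b:]]
    out_mean = float(outside.mean()) if outside.size else 0.0
    width_cm = (b - a) * ctx.bin_size_cm

    passes_width = width_cm >= min_width_cm
    if out_mean <= 0:
        passes_ratio = in_mean > 0
    else:
        passes_ratio = in_mean >= ratio * out_mean

    in_field = (ctx.bins_kept >= a) & (ctx.bins_kept < b)
    n_in = int(in_field.sum())
    coverage = (float(transient_mask[ctx.keep][in_field].mean())
                if n_in else 0.0)
    return PlaceField(
        bin_start=a, bin_end=b, width_cm=width_cm,
        in_field_mean=in_mean, out_field_mean=out_mean,
        transient_coverage=coverage,
        passes_width=passes_width, passes_ratio=passes_ratio,
        passes_coverage=coverage >= min_coverage,
    )


def detect_place_fields(trace: np.ndarray, ctx: DetectionContext,
                        sigma: float | None = None) -> list[PlaceField]:
    """Run screening + the three criteria on one neuron's ΔF/F trace."""
    if sigma is None:
        sigma = noise_sigma_fwhm(trace)
    row = _trace_to_smoothed_map(trace, ctx)
    if np.isnan(row).any():
        return []
    tmask = _transient_mask(len(trace), significant_transients(
        trace, sigma, ctx.frame_rate_hz))
    return [field_criteria(run, row, tmask, ctx)
            for run in candidate_fields(row)]


def _any_passing(trace: np.ndarray, ctx: DetectionContext, sigma: float) -> bool:
    row = _trace_to_smoothed_map(trace, ctx)
    if np.isnan(row).any():
        return False
    runs = candidate_fields(row)
    if not runs:
        return False
    tmask = _transient_mask(len(trace), significant_transients(
        trace, sigma, ctx.frame_rate_hz))
    return any(field_criteria(r, row, tmask, ctx).passes for r in runs)


def bootstrap_pvalue(trace: np.ndarray, ctx: DetectionContext,
                     sigma: float | None = None, chunk_frames: int = 50,
                     n_shuffles: int = 1000, seed=None) -> float:
    """Chunk-shuffle significance of place-field detection.

    The trace is split into 50-frame pieces (a final partial piece is kept as
    its own chunk), the pieces are permuted, and the full detection pipeline
    (screening + all three criteria) is re-run on each shuffled trace against
    the unchanged behaviour. p_pf is the fraction of shuffles producing at
    least one passing field; tonic activity that passes regardless of
    temporal order therefore earns p_pf = 1. The noise σ is estimated once —
    chunk permutation leaves the value distribution unchanged.
    """
    trace = np.asarray(trace, dtype=float)
    if len(trace) < 2 * chunk_frames:
        raise ValueError("trace too short to chunk-shuffle")
    if sigma is None:
        sigma = noise_sigma_fwhm(trace)
    rng = np.random.default_rng(seed)
    n_chunks = int(np.ceil(len(trace) / chunk_frames))
    chunks = [trace[k * chunk_frames:(k + 1) * chunk_frames]
              for k in range(n_chunks)]
    passing = 0
    for _ in range(n_shuffles):
        order = rng.permutation(n_chunks)
        shuffled = np.concatenate([chunks[k] for k in order])
        if _any_passing(shuffled, ctx, sigma):
            passing += 1
    return passing / n_shuffles


def classify_place_cell(trace: np.ndarray, ctx: DetectionContext,
                        chunk_frames: int = 50, n_shuffles: int = 1000,
                        seed=None, alpha: float = 0.05):
    """Full per-neuron classification: fields, p_pf and the verdict.

    Returns ``(is_pc, fields, p_pf)``. The bootstrap only needs to run when
    the real map already contains a passing field — without one the cell can
    never be a place cell, whatever p_pf would be.
    """
    sigma = noise_sigma_fwhm(trace)
    fields = detect_place_fields(trace, ctx, sigma=sigma)
    if not any(f.passes for f in fields):
        return False, fields, np.nan
    p = bootstrap_pvalue(trace, ctx, sigma=sigma, chunk_frames=chunk_frames,
                         n_shuffles=n_shuffles, seed=seed)
    for f in fields:
        f.p_pf = p
    return p <= alpha, fields, p


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

_CLIP = 1.0 - 1e-6


def nan_pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r over bins valid in both vectors; NaN when undefined."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 2:
        return np.nan
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def fisher_mean(rs) -> float:
    """Average correlations on the Fisher-z scale, back-transform to r.

    Values are clipped to ±(1 − 1e−6) before atanh so perfect correlations
    stay finite; NaNs are dropped.
    """
    rs = np.asarray(rs, dtype=float)
    rs = rs[~np.isnan(rs)]
    if rs.size == 0:
        return np.nan
    z = np.arctanh(np.clip(rs, -_CLIP, _CLIP))
    return float(np.tanh(z.mean()))


def within_session_stability(per_trial_maps: np.ndarray) -> float:
    """Fisher-averaged correlation of trial-half and odd/even split maps.

    ``per_trial_maps`` is trials × bins for one neuron. The first/second-half
    and odd/even trial-mean maps are correlated over bins and the two
    coefficients Fisher-averaged. Fewer than 4 trials → NaN.
    """
    maps = np.asarray(per_trial_maps, dtype=float)
    n = maps.shape[0]
    if n < 4:
        return np.nan
    with np.errstate(invalid="ignore"):
        first = np.nanmean(maps[: n // 2], axis=0)
        second = np.nanmean(maps[n // 2:], axis=0)
        odd = np.nanmean(maps[1::2], axis=0)
        even = np.nanmean(maps[0::2], axis=0)
    r_half = nan_pearson(first, second)
    r_oe = nan_pearson(odd, even)
    return fisher_mean([r_half, r_oe])


def cross_session_stability(maps_by_day: dict, phase_days,
                            pair_gap_days: int = 3) -> float:
    """Phase stability score: Fisher-mean map correlation over 3-day pairs.

    ``maps_by_day`` maps day -> the neuron's (smoothed trial-mean) spatial
    map. All session pairs inside the phase separated by exactly
    ``pair_gap_days`` contribute; no qualifying pair → NaN.
    """
    days = sorted(d for d in phase_days if d in maps_by_day)
    rs = [nan_pearson(maps_by_day[d1], maps_by_day[d2])
          for i, d1 in enumerate(days) for d2 in days[i + 1:]
          if abs(d2 - d1) == pair_gap_days]
    return fisher_mean(rs) if rs else np.nan


def classify_stability(scores_by_phase: dict, baseline_median: float,
                       is_pc_by_phase: dict,
                       healthy_persistent: bool | None = None) -> dict:
    """Per-phase functional class from stability scores and PC status.

    Place cells strictly above the network's pre-injection median stability
    are ``stable_pc``; at or below it (ties included), ``unstable_pc``;
    non-place-cells are ``noncoding``; a place cell without a stability score
    in a phase is ``absent`` there. ``healthy_persistent`` optionally gates
    the healthy-phase stable label on the neuron having held a place field at
    the same position across all healthy sessions (the persistence reading of
    "stable"); by default only the median split applies.
    """
    out = {}
    for phase, is_pc in is_pc_by_phase.items():
        if not is_pc:
            out[phase] = "noncoding"
            continue
        score = scores_by_phase.get(phase, np.nan)
        if score is None or np.isnan(score):
            out[phase] = "absent"
            continue
        stable = score > baseline_median
        if stable and phase == "healthy" and healthy_persistent is not None:
            stable = bool(healthy_persistent)
        out[phase] = "stable_pc" if stable else "unstable_pc"
    return out
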