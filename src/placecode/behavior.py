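"""Behavioural performance: lick histograms, spatial information, outcome groups.

Task performance in the corridor is scored by how spatially concentrated the
animal's licking is. Licks are binned into 120 position bins; the per-bin lick
probability λ_i (fraction of trials with at least one lick in that bin) and
the occupancy-weighted distribution p_i feed the spatial-information score

    SI = Σ_i p_i (λ_i / λ̄) log2(λ_i / λ̄),   λ̄ = Σ_i p_i λ_i  (bits)

which is 0 for spatially uniform licking and log2(N occupied bins) when all
licking collapses into one bin. Post-injection sessions are expressed as a
percentage of the mouse's mean healthy-baseline SI, and mice are sorted into
Recovery / No-Recovery / pooled-sham outcome groups by whether that relative
performance stays at or below 75% in the early and late post-injection phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .corridor import CorridorConfig
from .session import SessionData

__all__ = [
    "LickHistogram",
    "lick_histogram",
    "spatial_information",
    "relative_performance",
    "classify_outcome",
]


@dataclass
class LickHistogram:
    """Per-bin lick probability and occupancy for one session.

    ``lambda_i[k]`` is the fraction of trials with >= 1 lick in bin k;
    ``t_i[k]`` the occupancy time (s); ``p_i`` the normalised occupancy.
    Never-visited bins have t_i = p_i = 0 and drop out of all sums.
    """

    lambda_i: np.ndarray
    t_i: np.ndarray

    @property
    def p_i(self) -> np.ndarray:
        total = self.t_i.sum()
        return self.t_i / total if total > 0 else np.zeros_like(self.t_i)

    @property
    def lambda_bar(self) -> float:
        return float(np.sum(self.p_i * self.lambda_i))


def lick_histogram(session: SessionData, config: CorridorConfig) -> LickHistogram:
    """Bin licks and occupancy into the fine behavioural grid.

    Occupancy counts every in-trial frame (no velocity filter: the behaviour
    metric scores where the animal licks, including while standing at a
    spout); lick probability per bin is the fraction of trials with at least
    one lick there.
    """
    if session.n_trials < 1:
        raise ValueError("lick_histogram requires at least one trial")
    n = config.lick_bin_count
    trial = session.trial_of_frame()
    in_trial = trial >= 0
    bins = config.lick_bin_of(session.position_cm)

    t_i = np.bincount(bins[in_trial], minlength=n) / session.frame_rate_hz

    hit = np.zeros((session.n_trials, n), dtype=bool)
    lf = session.lick_frames[in_trial[session.lick_frames]]
    hit[trial[lf], bins[lf]] = True
    lam = hit.mean(axis=0)
    return LickHistogram(lambda_i=lam, t_i=t_i.astype(float))


def spatial_information(hist: LickHistogram) -> float:
    """Spatial information of a lick histogram, in bits.

    Bins with zero occupancy (p_i = 0) and bins with λ_i = 0 contribute
    nothing. A session without any licks has λ̄ = 0; its SI is defined as 0
    (with a warning) so impaired, non-licking sessions survive the pipeline.
    """
    p = hist.p_i
    lam = hist.lambda_i
    lbar = hist.lambda_bar
    if lbar == 0:
        warnings.warn("no licks in session: spatial information set to 0")
        return 0.0
    mask = (p > 0) & (lam > 0)
    ratio = lam[mask] / lbar
    return float(np.sum(p[mask] * ratio * np.log2(ratio)))


def relative_performance(si_by_session: dict, healthy_sessions) -> dict:
    """Express each session's SI as percent of the mean healthy-baseline SI."""
    healthy = [si_by_session[s] for s in healthy_sessions]
    if not healthy:
        raise ValueError("at least one healthy session is required")
    base = float(np.mean(healthy))
    if base == 0:
        raise ValueError("healthy-baseline mean SI is zero; relative performance undefined")
    return {s: 100.0 * v / base for s, v in si_by_session.items()}


def classify_outcome(early_mean_pct: float, late_mean_pct: float,
                     injected: bool, sphere_override: bool | None = None) -> str:
    """Assign the outcome group from phase-mean relative performance.

    Injected mice at or below 75% of baseline in both post phases are
    ``no_recovery``; at or below 75% only early (recovering late) are
    ``recovery``; injected mice never dropping below threshold are pooled with
    shams (``pooled_sham``). Pooling additionally requires that histology did
    not find significantly more microspheres than in shams; that evidence is
    outside this pipeline, so it enters as the optional ``sphere_override``
    flag — passing False blocks pooling and raises, since such a mouse fits
    none of the defined groups and must be excluded by the caller.
    Non-injected mice are ``sham``. The 75% boundary is inclusive: a tie goes
    to the impaired label.
    """
    if not injected:
        return "sham"
    for v, name in ((early_mean_pct, "early"), (late_mean_pct, "late")):
        if v is None or not np.isfinite(v):
            raise ValueError(f"missing {name}-phase relative performance")
    if early_mean_pct <= 75.0 and late_mean_pct <= 75.0:
        return "no_recovery"
    if early_mean_pct <= 75.0:
        return "recovery"
    if sphere_override is False:
        raise ValueError(
            "mouse kept >75% performance but has elevated sphere counts; "
            "it cannot be pooled with shams and fits no outcome group")
    return "pooled_sham"
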