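"""Gaussian naive-Bayes position decoding from population ΔF/F.

The decoder estimates the animal's corridor bin at each frame as

    x̂(t) = argmax_x  occ(x) · Π_i  p_i(x, t) / max_x p_i(x, t)

where p_i(x, t) is a Gaussian likelihood of neuron i's smoothed activity
S_i(t) (mean ΔF/F over t ± 0.5 s) under its training tuning curve
(cross-trial mean μ_i(x) and SD σ_i(x) of the smoothed per-trial spatial
maps), and occ(x) is the occupancy prior from the training frames. Per-bin
SDs below the neuron's average SD are floored to that average, which keeps
occasionally-quiet bins from dominating the product. Each model uses the top
100 neurons by within-session stability. All products run in log space.

Evaluation modes: leave-one-out across trials within a session, and
cross-session (fit on one session, decode another over tracked neurons).
Chance levels come from shuffling the bin identity of the training maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corridor import CorridorConfig
from .placecells import within_session_stability
from .session import SessionData
from .spatial import _interp_nan, bin_activity, smooth_map

__all__ = [
    "DecoderModel",
    "DecodedTrajectory",
    "fit_decoder",
    "decode_frames",
    "decoder_metrics",
    "loo_within_session",
    "cross_session_decode",
    "empirical_chance",
]

SIGMA_FLOOR = 1e-6   # ΔF/F; guards log-likelihoods against zero variance


@dataclass
class DecoderModel:
    """Per-neuron tuning statistics and occupancy prior of the training set."""

    neuron_ids: np.ndarray   # indices into the session's dff rows
    mu: np.ndarray           # neurons × bins
    sigma: np.ndarray        # neurons × bins, floored > 0
    occ: np.ndarray          # occupancy probability per bin, sums to 1
    config: CorridorConfig

    def __post_init__(self):
        assert np.all(self.sigma > 0), "sigma must be floored positive"


@dataclass
class DecodedTrajectory:
    """Frame-wise predictions and (log-domain) decoder confidence."""

    x_hat: np.ndarray          # predicted bin per frame
    log_posterior: np.ndarray  # frames × bins, unnormalised
    S: np.ndarray              # neurons × frames smoothed activity used
    delta_t_s: float

    @property
    def confidence(self) -> np.ndarray:
        """Posterior per frame, normalised to max 1 (arbitrary units)."""
        m = self.log_posterior.max(axis=1, keepdims=True)
        return np.exp(self.log_posterior - m)


def fit_decoder(per_trial_maps: np.ndarray, occupancy_frames: np.ndarray,
                stability_scores: np.ndarray, config: CorridorConfig,
                max_neurons: int = 100,
                neuron_pool: np.ndarray | None = None) -> DecoderModel:
    """Fit tuning statistics from smoothed per-trial training maps.

    ``per_trial_maps`` is trials × neurons × bins (already smoothed; missing
    bins NaN). μ and σ are the across-trial mean and SD per bin; bins a
    neuron's training trials never covered are interpolated from neighbours.
    Per-neuron SD flooring replaces any bin SD below that neuron's average
    bin SD with the average. Neurons are ranked by within-session stability
    and the ``max_neurons`` most stable kept; ``neuron_pool`` restricts the
    candidates (e.g. to neurons tracked into the decoding session).
    """
    maps = np.asarray(per_trial_maps, dtype=float)
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 training trials to estimate cross-trial SD")
    n_neurons = maps.shape[1]
    pool = (np.arange(n_neurons) if neuron_pool is None
            else np.asarray(neuron_pool, dtype=int))
    scores = np.asarray(stability_scores, dtype=float)[pool]
    order = pool[np.argsort(-np.nan_to_num(scores, nan=-np.inf), kind="stable")]
    keep = order[:max_neurons]

    with np.errstate(invalid="ignore"):
        mu = np.nanmean(maps[:, keep, :], axis=0)
        sigma = np.nanstd(maps[:, keep, :], axis=0)
    mu = np.vstack([_interp_nan(row) for row in mu])
    mu = np.nan_to_num(mu, nan=0.0)
    sigma = np.nan_to_num(sigma, nan=0.0)

    # per-neuron flooring: bins quieter than the neuron's average SD get the average
    mean_sd = sigma.mean(axis=1, keepdims=True)
    sigma = np.where(sigma < mean_sd, np.broadcast_to(mean_sd, sigma.shape), sigma)
    if np.any(sigma.max(axis=1) <= 0):
        import warnings
        warnings.warn("neuron(s) with zero cross-trial variance: sigma floored to epsilon")
    sigma = np.maximum(sigma, SIGMA_FLOOR)

    occ = np.asarray(occupancy_frames, dtype=float)
    total = occ.sum()
    if total <= 0:
        raise ValueError("empty training occupancy")
    return DecoderModel(neuron_ids=keep, mu=mu, sigma=sigma,
                        occ=occ / total, config=config)


def _smoothed_activity(dff: np.ndarray, frame_rate_hz: float,
                       delta_t_s: float) -> np.ndarray:
    """Mean ΔF/F over t ± Δt, window truncated at the record edges."""
    half = int(round(delta_t_s * frame_rate_hz))
    n = dff.shape[1]
    csum = np.cumsum(np.concatenate([np.zeros((dff.shape[0], 1)), dff], axis=1),
                     axis=1)
    t = np.arange(n)
    lo = np.maximum(t - half, 0)
    hi = np.minimum(t + half + 1, n)
    return (csum[:, hi] - csum[:, lo]) / (hi - lo)


def decode_frames(model: DecoderModel, dff: np.ndarray,
                  frame_rate_hz: float = 30.0, delta_t_s: float = 0.5,
                  chunk: int = 512) -> DecodedTrajectory:
    """Decode every frame of ``dff`` (rows = all session neurons).

    Likelihoods are evaluated in log space; each neuron's row is normalised
    by its maximum over bins (making the per-frame row maximum exactly 1 in
    linear units) and multiplied with the occupancy prior. Argmax ties break
    to the lowest bin index. Zero-occupancy bins are never predicted.
    """
    dff = np.asarray(dff, dtype=float)
    if not np.all(np.isfinite(dff)):
        raise ValueError("dff contains non-finite values")
    S_all = _smoothed_activity(dff, frame_rate_hz, delta_t_s)
    S = S_all[model.neuron_ids]               # neurons × frames
    mu, sigma = model.mu, model.sigma
    n_frames = S.shape[1]
    n_bins = mu.shape[1]
    with np.errstate(divide="ignore"):
        log_occ = np.log(model.occ)
    const = -0.5 * np.log(2 * np.pi * sigma ** 2)   # neurons × bins

    logpost = np.empty((n_frames, n_bins))
    for a in range(0, n_frames, chunk):
        b = min(a + chunk, n_frames)
        resid = S[:, a:b, None] - mu[:, None, :]          # neurons × f × bins
        ll = const[:, None, :] - resid ** 2 / (2 * sigma[:, None, :] ** 2)
        ll -= ll.max(axis=2, keepdims=True)               # per-neuron max-normalisation
        logpost[a:b] = log_occ[None, :] + ll.sum(axis=0)
    x_hat = np.argmax(logpost, axis=1)
    return DecodedTrajectory(x_hat=x_hat, log_posterior=logpost, S=S,
                             delta_t_s=delta_t_s)


def decoder_metrics(x_hat: np.ndarray, true_bins: np.ndarray,
                    config: CorridorConfig) -> dict:
    """Exact-bin accuracy and reward-zone sensitivity.

    Sensitivity is computed over frames whose true bin lies inside any RZ:
    the fraction whose predicted bin is also inside an RZ (not necessarily
    the same one). No RZ frames → sensitivity NaN.
    """
    x_hat = np.asarray(x_hat)
    true_bins = np.asarray(true_bins)
    if x_hat.shape != true_bins.shape:
        raise ValueError("prediction / truth length mismatch")
    acc = float(np.mean(x_hat == true_bins))
    rz = np.zeros(config.n_bins, dtype=bool)
    rz[config.rz_bins()] = True
    in_rz = rz[true_bins]
    sens = float(np.mean(rz[x_hat[in_rz]])) if in_rz.any() else np.nan
    return {"accuracy": acc, "sensitivity": sens}


def _session_true_bins(session: SessionData, config: CorridorConfig,
                       frames: np.ndarray) -> np.ndarray:
    return config.bin_of(session.position_cm[frames])


def _training_occupancy(session: SessionData, config: CorridorConfig,
                        trials, velocity_threshold: float = 5.0) -> np.ndarray:
    trial = session.trial_of_frame()
    keep = np.isin(trial, trials) & (session.velocity_cm_s >= velocity_threshold)
    bins = config.bin_of(session.position_cm)
    return np.bincount(bins[keep], minlength=config.n_bins)


def loo_within_session(session: SessionData, config: CorridorConfig,
                       max_neurons: int = 100, delta_t_s: float = 0.5) -> dict:
    """Leave-one-out decoding: each trial decoded from the remaining trials.

    Returns per-fold metrics and their session mean. Frames inside the
    held-out trial are all decoded, including those the velocity filter
    would exclude from map building.
    """
    if session.n_trials < 3:
        raise ValueError("leave-one-out decoding needs at least 3 trials")
    amap = bin_activity(session, config)
    pt = amap.smoothed_per_trial                      # trials × neurons × bins
    trial = session.trial_of_frame()

    folds = []
    for held in range(session.n_trials):
        train = [t for t in range(session.n_trials) if t != held]
        stability = np.array([
            within_session_stability(pt[train, j, :])
            for j in range(session.n_neurons)
        ])
        model = fit_decoder(pt[train], _training_occupancy(session, config, train),
                            stability, config, max_neurons=max_neurons)
        frames = np.nonzero(trial == held)[0]
        traj = decode_frames(model, session.dff[:, frames],
                             session.frame_rate_hz, delta_t_s)
        m = decoder_metrics(traj.x_hat, _session_true_bins(session, config, frames),
                            config)
        m["trial"] = held
        folds.append(m)
    mean = {k: float(np.nanmean([f[k] for f in folds]))
            for k in ("accuracy", "sensitivity")}
    return {"folds": folds, "accuracy": mean["accuracy"],
            "sensitivity": mean["sensitivity"]}


def fit_session_decoder(session: SessionData, config: CorridorConfig,
                        max_neurons: int = 100,
                        neuron_pool: np.ndarray | None = None) -> DecoderModel:
    """Fit a decoder on all trials of a session (for cross-session use)."""
    amap = bin_activity(session, config)
    pt = amap.smoothed_per_trial
    stability = np.array([within_session_stability(pt[:, j, :])
                          for j in range(session.n_neurons)])
    return fit_decoder(pt, amap.occupancy_frames, stability, config,
                       max_neurons=max_neurons, neuron_pool=neuron_pool)


def cross_session_decode(train_session: SessionData, test_session: SessionData,
                         config: CorridorConfig, registry=None,
                         train_id=None, test_id=None,
                         max_neurons: int = 100, delta_t_s: float = 0.5) -> dict:
    """Fit on one full session and decode every in-trial frame of another.

    With a :class:`CellRegistry` the model is restricted to neurons tracked
    in both sessions and the decoder reads the test session's ROI rows; with
    ``registry=None`` neuron rows are assumed to correspond 1:1 (the
    synthetic generator's convention).
    """
    if registry is not None:
        uids = registry.present_in([train_id, test_id])
        if uids.size == 0:
            raise ValueError("no tracked neurons shared between the sessions")
        pool_train = np.array([registry.roi_index(u, train_id) for u in uids])
        rows_test = np.array([registry.roi_index(u, test_id) for u in uids])
        remap = dict(zip(pool_train, rows_test))
    else:
        if train_session.n_neurons != test_session.n_neurons:
            raise ValueError("sessions have different populations; provide a registry")
        pool_train = np.arange(train_session.n_neurons)
        remap = None

    model = fit_session_decoder(train_session, config, max_neurons=max_neurons,
                                neuron_pool=pool_train)
    if remap is not None:
        model = DecoderModel(
            neuron_ids=np.array([remap[i] for i in model.neuron_ids]),
            mu=model.mu, sigma=model.sigma, occ=model.occ, config=config)
    trial = test_session.trial_of_frame()
    frames = np.nonzero(trial >= 0)[0]
    traj = decode_frames(model, test_session.dff[:, frames],
                         test_session.frame_rate_hz, delta_t_s)
    m = decoder_metrics(traj.x_hat,
                        _session_true_bins(test_session, config, frames), config)
    m["n_neurons"] = len(model.neuron_ids)
    return m


def empirical_chance(model: DecoderModel, dff: np.ndarray,
                     true_bins: np.ndarray, config: CorridorConfig,
                     n_shuffles: int = 500, seed=None,
                     frame_rate_hz: float = 30.0, delta_t_s: float = 0.5) -> dict:
    """Chance metrics from shuffling the training maps' bin identity.

    Per shuffle one permutation of the spatial bins is applied consistently
    to every neuron's tuning curve and to the occupancy prior — preserving
    the joint tuning structure while destroying the position mapping — and
    the decoder is re-evaluated. Because the likelihood depends on the bin
    only through (μ_i(x), σ_i(x), occ(x)), permuting those arrays equals
    permuting the columns of the unshuffled per-frame log-score matrix, so
    the matrix is computed once and each shuffle reduces to a column gather.
    """
    rng = np.random.default_rng(seed)
    traj = decode_frames(model, dff, frame_rate_hz, delta_t_s)
    M0 = traj.log_posterior                     # includes occ; frames × bins
    accs, senss = [], []
    for _ in range(n_shuffles):
        perm = rng.permutation(config.n_bins)
        # shuffled model's score at bin x equals M0 at perm[x]
        pred = np.argmax(M0[:, perm], axis=1)
        m = decoder_metrics(pred, true_bins, config)
        accs.append(m["accuracy"])
        senss.append(m["sensitivity"])
    senss = np.asarray(senss, dtype=float)
    any_sens = np.any(~np.isnan(senss))
    return {"accuracy": float(np.mean(accs)),
            "sensitivity": float(np.nanmean(senss)) if any_sens else np.nan,
            "accuracy_sd": float(np.std(accs)),
            "sensitivity_sd": float(np.nanstd(senss)) if any_sens else np.nan,
            "n_shuffles": n_shuffles}
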