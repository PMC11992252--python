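"""Bayesian position decoder: fitting, flooring, worked examples, evaluation."""

import numpy as np
import pytest
from scipy.stats import norm

from placecode import (CorridorConfig, cross_session_decode, decode_frames,
                       decoder_metrics, empirical_chance, fit_decoder,
                       loo_within_session)
from placecode.decoding import DecoderModel, fit_session_decoder, _session_true_bins

from conftest import make_session


def _model(mu, sigma, occ, config=None):
    mu = np.asarray(mu, float)
    cfg = config or CorridorConfig(length_cm=float(len(occ) * 5), bin_size_cm=5.0,
                                   rz_centers_cm=(), lick_bin_count=10)
    return DecoderModel(neuron_ids=np.arange(mu.shape[0]), mu=mu,
                        sigma=np.asarray(sigma, float),
                        occ=np.asarray(occ, float) / np.sum(occ), config=cfg)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_sd_flooring_rule_by_hand():
    """Per-bin SDs (0.1, 0.3, 0.2): mean 0.2 -> the 0.1 bin floors to 0.2."""
    s = np.sqrt(3.0 / 2.0)          # std of (-a, 0, a) is a*sqrt(2/3)
    trials = np.zeros((3, 1, 3))
    for b, sd in enumerate((0.1, 0.3, 0.2)):
        trials[:, 0, b] = np.array([-1.0, 0.0, 1.0]) * sd * s
    model = fit_decoder(trials, np.ones(3), np.array([1.0]),
                        CorridorConfig(length_cm=15, bin_size_cm=5,
                                       rz_centers_cm=(), lick_bin_count=3))
    np.testing.assert_allclose(model.sigma[0], [0.2, 0.3, 0.2], atol=1e-9)


def test_identical_trials_floor_to_epsilon():
    trials = np.tile(np.linspace(0, 1, 4), (3, 1, 1))       # 3 identical trials
    with pytest.warns(UserWarning, match="zero cross-trial variance"):
        model = fit_decoder(trials, np.ones(4), np.array([0.5]),
                            CorridorConfig(length_cm=20, bin_size_cm=5,
                                           rz_centers_cm=(), lick_bin_count=4))
    assert (model.sigma > 0).all()


def test_top_stability_neurons_kept():
    rng = np.random.default_rng(0)
    trials = rng.random((3, 150, 8))
    scores = np.arange(150, dtype=float)
    model = fit_decoder(trials, np.ones(8), scores,
                        CorridorConfig(length_cm=40, bin_size_cm=5,
                                       rz_centers_cm=(), lick_bin_count=8))
    assert len(model.neuron_ids) == 100
    assert set(model.neuron_ids) == set(range(50, 150))     # the 100 most stable


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def test_posterior_ratio_worked_example():
    """2 neurons, 2 bins, σ = 0.5, S = (0.9, 0.1): posterior ratio e^3.2."""
    model = _model(mu=[[1.0, 0.0], [0.0, 1.0]],
                   sigma=np.full((2, 2), 0.5), occ=[0.5, 0.5])
    dff = np.array([[0.9], [0.1]])
    traj = decode_frames(model, dff, frame_rate_hz=30.0, delta_t_s=0.0)
    ratio = np.exp(traj.log_posterior[0, 0] - traj.log_posterior[0, 1])
    assert ratio == pytest.approx(np.exp(3.2), rel=1e-9)
    assert traj.x_hat[0] == 0


def test_one_hot_prior_dominates():
    model = _model(mu=np.zeros((2, 4)), sigma=np.full((2, 4), 0.5),
                   occ=[0.0, 0.0, 1.0, 0.0])
    traj = decode_frames(model, np.zeros((2, 5)))
    assert (traj.x_hat == 2).all()


def test_log_space_matches_direct_product():
    """Small instance: log-space decoding equals the naive probability product."""
    rng = np.random.default_rng(1)
    n_neurons, n_bins, n_frames = 5, 8, 20
    mu = rng.random((n_neurons, n_bins))
    sigma = rng.uniform(0.2, 0.6, (n_neurons, n_bins))
    occ = rng.random(n_bins)
    occ /= occ.sum()
    dff = rng.random((n_neurons, n_frames))
    model = _model(mu, sigma, occ)
    traj = decode_frames(model, dff, delta_t_s=0.0)

    S = dff
    post = np.empty((n_frames, n_bins))
    for t in range(n_frames):
        p = norm.pdf(S[:, t][:, None], loc=mu, scale=sigma)   # neurons × bins
        p = p / p.max(axis=1, keepdims=True)
        post[t] = occ * np.prod(p, axis=0)
    np.testing.assert_allclose(
        np.exp(traj.log_posterior - traj.log_posterior.max(axis=1, keepdims=True)),
        post / post.max(axis=1, keepdims=True), rtol=1e-9)
    np.testing.assert_array_equal(traj.x_hat, np.argmax(post, axis=1))


def test_max_normalised_likelihood_rows_peak_at_one():
    """Each neuron's normalised likelihood has maximum exactly 1 over bins."""
    rng = np.random.default_rng(2)
    mu = rng.random((3, 6))
    sigma = rng.uniform(0.2, 0.5, (3, 6))
    model = _model(mu, sigma, np.ones(6))
    S = rng.random((3, 4))
    ll = norm.pdf(S.T[:, :, None], loc=mu[None], scale=sigma[None])
    ll_norm = ll / ll.max(axis=2, keepdims=True)
    np.testing.assert_allclose(ll_norm.max(axis=2), 1.0)


def test_decoding_invariant_to_neuron_order():
    rng = np.random.default_rng(3)
    mu = rng.random((6, 10))
    sigma = rng.uniform(0.2, 0.5, (6, 10))
    occ = np.ones(10)
    dff = rng.random((6, 15))
    t1 = decode_frames(_model(mu, sigma, occ), dff, delta_t_s=0.0)
    perm = rng.permutation(6)
    t2 = decode_frames(_model(mu[perm], sigma[perm], occ), dff[perm], delta_t_s=0.0)
    np.testing.assert_array_equal(t1.x_hat, t2.x_hat)


# ---------------------------------------------------------------------------
# metrics and evaluation modes
# ---------------------------------------------------------------------------

def test_metrics_counting(corridor):
    truth = np.arange(10)
    assert decoder_metrics(truth, truth, corridor)["accuracy"] == 1.0
    pred = truth.copy()
    pred[4:] = 0
    m = decoder_metrics(pred, truth, corridor)
    # bins 0..3 and bin 0 predictions: 4 of 10 exact
    assert m["accuracy"] == pytest.approx(0.4)


def test_sensitivity_rz_confusion_allowed(corridor):
    rz = corridor.rz_bins()
    truth = np.array([rz[0], rz[0], 0, 1])    # bins 0,1 lie before the first RZ
    pred = np.array([rz[-1], 0, 0, 1])        # a wrong RZ still counts; non-RZ doesn't
    m = decoder_metrics(pred, truth, corridor)
    assert m["sensitivity"] == pytest.approx(0.5)
    # no RZ frames -> sensitivity undefined
    assert np.isnan(decoder_metrics(np.array([0]), np.array([0]), corridor)["sensitivity"])


def test_loo_decodes_well_above_chance(pc_session, corridor):
    """A stable 120-PC population decodes far above the 1/80 chance level."""
    s, _ = pc_session
    res = loo_within_session(s, corridor)
    assert res["accuracy"] > 10 * (1.0 / corridor.n_bins)
    assert res["sensitivity"] > 0.6


def test_loo_requires_three_trials(corridor, pc_session):
    s, _ = pc_session
    from placecode.session import SessionData
    a, b = s.trial_bounds[0]
    short = SessionData(dff=s.dff[:, :b], position_cm=s.position_cm[:b],
                        velocity_cm_s=s.velocity_cm_s[:b], lick_frames=[],
                        reward_frames=[], trial_bounds=[(a, b)])
    with pytest.raises(ValueError, match="3 trials"):
        loo_within_session(short, corridor)


def test_cross_session_self_consistency(pc_session, corridor):
    """Decoding a session with itself as training matches plain decoding."""
    s, _ = pc_session
    m = cross_session_decode(s, s, corridor)
    assert m["accuracy"] > 10 * (1.0 / corridor.n_bins)


def test_empirical_chance_uniform_toy():
    """4 equally occupied bins: shuffle chance accuracy ≈ 1/4."""
    cfg = CorridorConfig(length_cm=20, bin_size_cm=5, rz_centers_cm=(),
                         lick_bin_count=4)
    rng = np.random.default_rng(4)
    mu = rng.random((5, 4))
    sigma = np.full((5, 4), 0.3)
    model = _model(mu, sigma, np.ones(4), config=cfg)
    dff = rng.random((5, 400))
    truth = rng.integers(0, 4, 400)
    ch = empirical_chance(model, dff, truth, cfg, n_shuffles=400, seed=5,
                          delta_t_s=0.0)
    se = ch["accuracy_sd"] / np.sqrt(ch["n_shuffles"])
    assert abs(ch["accuracy"] - 0.25) <= 3 * se + 1e-3
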