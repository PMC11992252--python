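"""Place-field detection criteria, bootstrap significance, stability scores."""

import numpy as np
import pytest

from placecode import (bootstrap_pvalue, candidate_fields, classify_place_cell,
                       classify_stability, cross_session_stability,
                       detect_place_fields, detection_context, field_criteria,
                       fisher_mean, noise_sigma_fwhm, significant_transients,
                       within_session_stability)
from placecode.placecells import _transient_mask

from conftest import make_session


# ---------------------------------------------------------------------------
# noise level and transients
# ---------------------------------------------------------------------------

def test_noise_sigma_recovers_gaussian_sd():
    rng = np.random.default_rng(0)
    trace = rng.normal(0, 0.1, 5000)
    assert noise_sigma_fwhm(trace) == pytest.approx(0.1, rel=0.10)


def test_noise_sigma_robust_to_sparse_transients():
    """Transients in <5% of frames barely move the FWHM noise estimate."""
    rng = np.random.default_rng(1)
    trace = rng.normal(0, 0.1, 5000)
    idx = rng.choice(5000, 200, replace=False)
    trace[idx] += rng.uniform(0.5, 2.0, 200)
    assert noise_sigma_fwhm(trace) == pytest.approx(0.1, rel=0.15)


def test_noise_sigma_constant_trace():
    with pytest.warns(UserWarning, match="constant"):
        assert noise_sigma_fwhm(np.ones(200)) == 0.0


@pytest.mark.parametrize("run_len,expected", [(20, 1), (10, 0)])
def test_transient_minimum_duration(run_len, expected):
    """At 30 Hz a transient must span ≥ 15 frames (0.5 s) above 3σ."""
    trace = np.zeros(300)
    trace[100:100 + run_len] = 0.4       # 4σ for σ = 0.1
    intervals = significant_transients(trace, sigma=0.1, frame_rate_hz=30.0)
    assert len(intervals) == expected
    if expected:
        assert intervals[0] == (100, 100 + run_len)


def test_no_transients_below_threshold():
    assert significant_transients(np.full(300, 0.2), sigma=0.1) == []


# ---------------------------------------------------------------------------
# candidate screening and criteria
# ---------------------------------------------------------------------------

def test_candidate_fields_flat_and_bumps():
    assert candidate_fields(np.full(80, 0.3)) == []
    row = np.zeros(80)
    row[30:36] = 1.0
    assert candidate_fields(row) == [(30, 36)]
    row[60:65] = 1.0
    assert candidate_fields(row) == [(30, 36), (60, 65)]


def _toy_ctx(n_bins=80, frames_per_bin=10):
    """One 'trial' visiting every bin for frames_per_bin frames."""
    from placecode import CorridorConfig
    from placecode.session import SessionData
    cfg = CorridorConfig()
    n = n_bins * frames_per_bin
    pos = np.repeat((np.arange(n_bins) + 0.5) * cfg.bin_size_cm, frames_per_bin)
    s = SessionData(dff=np.zeros((1, n)), position_cm=pos,
                    velocity_cm_s=np.full(n, 10.0), lick_frames=[],
                    reward_frames=[], trial_bounds=[(0, n)])
    return cfg, s, detection_context(s, cfg)


def test_field_criteria_width():
    cfg, s, ctx = _toy_ctx()
    row = np.zeros(80)
    row[10:12] = 1.0          # 10 cm wide
    f = field_criteria((10, 12), row, np.zeros(s.n_frames, bool), ctx)
    assert not f.passes_width and f.width_cm == 10.0
    f = field_criteria((10, 13), row, np.zeros(s.n_frames, bool), ctx)
    assert f.passes_width


def test_field_criteria_in_out_ratio():
    cfg, s, ctx = _toy_ctx()
    row = np.full(80, 0.1)
    row[10:16] = 0.6           # exactly 6x the outside mean
    f = field_criteria((10, 16), row, np.zeros(s.n_frames, bool), ctx)
    assert f.passes_ratio
    row[10:16] = 0.55
    f = field_criteria((10, 16), row, np.zeros(s.n_frames, bool), ctx)
    assert not f.passes_ratio


def test_field_criteria_nonpositive_outside_mean():
    """Undefined ratio: criterion 2 reads as in-field mean > 0."""
    cfg, s, ctx = _toy_ctx()
    row = np.zeros(80)
    row[10:16] = 0.6
    f = field_criteria((10, 16), row, np.zeros(s.n_frames, bool), ctx)
    assert f.passes_ratio and f.out_field_mean == 0.0


def test_field_criteria_transient_coverage():
    cfg, s, ctx = _toy_ctx()
    row = np.zeros(80)
    row[10:16] = 1.0
    in_field_frames = np.nonzero((ctx.bins_kept >= 10) & (ctx.bins_kept < 16))[0]
    mask = np.zeros(s.n_frames, bool)
    covered = in_field_frames[: int(0.15 * len(in_field_frames))]
    mask[covered] = True
    f = field_criteria((10, 16), row, mask, ctx)
    assert not f.passes_coverage and f.transient_coverage == pytest.approx(0.15, abs=0.02)
    mask[in_field_frames] = True
    f = field_criteria((10, 16), row, mask, ctx)
    assert f.passes_coverage


def test_detection_scale_invariance(mixed_session, corridor):
    """Multiplying a trace by a positive constant changes no verdict."""
    s, pop = mixed_session
    ctx = detection_context(s, corridor)
    j = int(np.nonzero(pop.classes == "stable_pc")[0][0])
    f1 = detect_place_fields(s.dff[j], ctx)
    f2 = detect_place_fields(s.dff[j] * 3.0, ctx)
    assert [(f.bin_start, f.bin_end, f.passes) for f in f1] == \
           [(f.bin_start, f.bin_end, f.passes) for f in f2]


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_constant_trace_yields_no_candidates():
    """A perfectly flat map cannot produce a place field."""
    cfg, s, ctx = _toy_ctx()
    assert detect_place_fields(np.full(s.n_frames, 1.0), ctx, sigma=0.1) == []


def test_shuffle_invariant_pass_gives_p_one():
    """When every chunk is an identical full trial, shuffling changes nothing.

    Chunk permutations then reproduce the original trace exactly, so a cell
    whose real map passes all three criteria passes in every shuffle and
    earns p_pf = 1.
    """
    from placecode import CorridorConfig
    from placecode.session import SessionData
    cfg = CorridorConfig()
    n_trials, fpt = 10, 50                     # trial length == chunk length
    pos_trial = np.linspace(0, 399.9, fpt)
    pos = np.tile(pos_trial, n_trials)
    # 20 consecutive hot frames per trial: long enough for a 0.5 s transient
    frame_idx = np.arange(fpt)
    trace_trial = ((frame_idx >= 20) & (frame_idx < 40)).astype(float)
    trace = np.tile(trace_trial, n_trials)
    s = SessionData(dff=trace[None, :], position_cm=pos,
                    velocity_cm_s=np.full(n_trials * fpt, 10.0),
                    lick_frames=[], reward_frames=[],
                    trial_bounds=[(k * fpt, (k + 1) * fpt) for k in range(n_trials)])
    ctx = detection_context(s, cfg)
    fields = detect_place_fields(trace, ctx, sigma=0.05)
    assert any(f.passes for f in fields)
    p = bootstrap_pvalue(trace, ctx, sigma=0.05, chunk_frames=fpt,
                         n_shuffles=50, seed=1)
    assert p == 1.0


def test_bootstrap_seeded_determinism(mixed_session, corridor):
    s, pop = mixed_session
    ctx = detection_context(s, corridor)
    j = int(np.nonzero(pop.classes == "stable_pc")[0][0])
    p1 = bootstrap_pvalue(s.dff[j], ctx, n_shuffles=30, seed=9)
    p2 = bootstrap_pvalue(s.dff[j], ctx, n_shuffles=30, seed=9)
    assert p1 == p2


def test_strong_place_cells_reach_significance(mixed_session, corridor):
    """Generated stable PCs pass detection with p_pf ≤ 0.05."""
    s, pop = mixed_session
    ctx = detection_context(s, corridor)
    stable = np.nonzero(pop.classes == "stable_pc")[0][:8]
    hits = 0
    for j in stable:
        ok, _, p = classify_place_cell(s.dff[j], ctx, n_shuffles=60, seed=int(j))
        hits += ok
    assert hits >= 7


def test_noise_cells_not_classified(mixed_session, corridor):
    s, pop = mixed_session
    ctx = detection_context(s, corridor)
    noise = np.nonzero(pop.classes == "noncoding")[0][:8]
    false_pos = sum(
        classify_place_cell(s.dff[j], ctx, n_shuffles=60, seed=int(j))[0]
        for j in noise)
    assert false_pos <= 1


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

def test_fisher_mean_worked_values():
    assert fisher_mean([0.5, 0.5]) == pytest.approx(0.5, abs=1e-9)
    # tanh((atanh .3 + atanh .7)/2)
    assert fisher_mean([0.3, 0.7]) == pytest.approx(0.52866, abs=1e-4)
    assert fisher_mean([0.2, 0.6]) == pytest.approx(0.42024, abs=1e-4)
    assert fisher_mean([1.0, 1.0]) > 0.999    # clipped, finite


def test_within_session_stability_identical_trials():
    rng = np.random.default_rng(4)
    template = rng.random(80)
    maps = np.tile(template, (8, 1))
    assert within_session_stability(maps) > 0.999


def test_within_session_stability_needs_four_trials():
    assert np.isnan(within_session_stability(np.random.default_rng(5).random((3, 80))))


def test_cross_session_pairs_use_three_day_gap():
    rng = np.random.default_rng(6)
    a = rng.random(80)
    maps = {0: a, 3: a.copy(), 6: -a + 1}        # (0,3) r=1; (3,6) r=-1; (0,6) gap 6 ignored
    score = cross_session_stability(maps, [0, 3, 6])
    assert score == pytest.approx(0.0, abs=1e-6)  # Fisher mean of ±1 (clipped)
    assert np.isnan(cross_session_stability({0: a, 6: a}, [0, 6]))


def test_stability_classification_median_split():
    scores = {"early_post": 0.5}
    assert classify_stability(scores, 0.5, {"early_post": True})["early_post"] \
        == "unstable_pc"                       # tie -> unstable
    assert classify_stability({"early_post": 0.7}, 0.5,
                              {"early_post": True})["early_post"] == "stable_pc"
    assert classify_stability({"early_post": 0.9}, 0.5,
                              {"early_post": False})["early_post"] == "noncoding"
    assert classify_stability({}, 0.5, {"late_post": True})["late_post"] == "absent"
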