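"""PVC matrices and curves, pairwise synchrony, RZ geometry."""

import numpy as np
import pytest

from placecode import (CorridorConfig, correlation_similarity, field_rz_geometry,
                       pair_euclidean_distance, pairwise_correlations,
                       phase_averaged_pairwise, pvc_curve_stats, pvc_matrix, rpp,
                       sync_pool_composition)


# ---------------------------------------------------------------------------
# population vector correlation
# ---------------------------------------------------------------------------

def test_pvc_self_diagonal_is_one():
    rng = np.random.default_rng(0)
    maps = rng.random((30, 80))
    m = pvc_matrix(maps, maps)
    np.testing.assert_allclose(np.diag(m), 1.0, atol=1e-12)


def test_pvc_scale_invariance():
    rng = np.random.default_rng(1)
    maps1 = rng.random((20, 40))
    maps2 = rng.random((20, 40))
    np.testing.assert_allclose(pvc_matrix(maps1, maps2),
                               pvc_matrix(maps1, 2.0 * maps2), atol=1e-12)
    np.testing.assert_allclose(pvc_matrix(maps1, maps1),
                               pvc_matrix(maps1, 2.0 * maps1), atol=1e-12)


def test_pvc_neuron_permutation_invariance():
    rng = np.random.default_rng(2)
    maps1 = rng.random((15, 20))
    maps2 = rng.random((15, 20))
    perm = rng.permutation(15)
    np.testing.assert_allclose(pvc_matrix(maps1, maps2),
                               pvc_matrix(maps1[perm], maps2[perm]), atol=1e-12)


def test_pvc_hand_example():
    """2 neurons, λ¹(x) = (1,0), λ²(y) = (1,1): PVC = 1/sqrt(2)."""
    maps1 = np.array([[1.0], [0.0]])
    maps2 = np.array([[1.0], [1.0]])
    assert pvc_matrix(maps1, maps2)[0, 0] == pytest.approx(1 / np.sqrt(2))


def test_pvc_zero_vector_is_missing():
    maps1 = np.array([[0.0, 1.0], [0.0, 1.0]])
    m = pvc_matrix(maps1, maps1)
    assert np.isnan(m[0, 0]) and m[1, 1] == pytest.approx(1.0)


def test_pvc_curve_and_slope():
    """A curve decaying 1.0 -> 0.8 over 0–100 cm has slope 0.2 per 100 cm."""
    cfg = CorridorConfig()
    n = cfg.n_bins
    x, y = np.indices((n, n))
    off = np.abs(x - y)
    matrix = np.clip(1.0 - 0.01 * off, 0.5, None)   # -0.01 per 5-cm offset
    res = pvc_curve_stats(matrix, cfg)
    assert len(res.curve) == 56
    assert res.y_intercept == pytest.approx(1.0)
    assert res.initial_slope == pytest.approx(0.2, abs=1e-9)
    flat = pvc_curve_stats(np.full((n, n), 0.7), cfg)
    assert flat.initial_slope == pytest.approx(0.0, abs=1e-12)


def test_self_session_intercept_is_one():
    rng = np.random.default_rng(3)
    maps = rng.random((25, 80)) + 0.1
    res = pvc_curve_stats(pvc_matrix(maps, maps), CorridorConfig())
    assert res.y_intercept == pytest.approx(1.0, abs=1e-12)


def test_rpp_values():
    assert rpp(np.full(20, 0.5)) == []
    # triangle wave: peaks at 1.0, valleys at 0.5 -> RPP = 0.5 each
    tri = np.array([0.5, 0.75, 1.0, 0.75, 0.5, 0.75, 1.0, 0.75, 0.5])
    vals = rpp(tri)
    assert len(vals) == 2
    np.testing.assert_allclose(vals, 0.5)
    with pytest.raises(ValueError):
        rpp(np.ones(3))


def test_periodic_population_peaks_near_rz_spacing(corridor):
    """Four evenly spread fields echo at the ~105 cm reward-zone spacing."""
    n_bins = corridor.n_bins
    bins = np.arange(n_bins) * corridor.bin_size_cm
    maps = []
    rng = np.random.default_rng(4)
    for _ in range(40):
        base = rng.choice(corridor.rz_centers_cm) + rng.normal(0, 4)
        m = np.zeros(n_bins)
        for c in corridor.rz_centers_cm:
            m += np.exp(-0.5 * ((bins - (base - corridor.rz_centers_cm[0] + c)
                                 % 400) / 10) ** 2)
        maps.append(m)
    maps = np.array(maps)
    res = pvc_curve_stats(pvc_matrix(maps, maps), corridor)
    peaks = [res.offsets_cm[k] for k in range(1, 55)
             if res.curve[k] > res.curve[k - 1] and res.curve[k] > res.curve[k + 1]]
    assert any(95 <= p <= 120 for p in peaks)


# ---------------------------------------------------------------------------
# pairwise structure
# ---------------------------------------------------------------------------

def test_pairwise_correlation_basics():
    a = np.array([1.0, -1, 1, -1, 1, -1])
    series = np.vstack([a, -a, np.ones(6)])
    m = pairwise_correlations(series)
    assert m[0, 0] == pytest.approx(1.0)
    assert m[0, 1] == pytest.approx(-1.0)
    assert np.isnan(m[2, 0]) and np.isnan(m[2, 2])   # zero-variance row missing


def test_pairwise_correlation_hand_value():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    y = np.array([0.0, 2.0, 1.0, 3.0])
    r = np.corrcoef(x, y)[0, 1]
    m = pairwise_correlations(np.vstack([x, y]))
    assert m[0, 1] == pytest.approx(r)


def test_sync_pool_constructed_composition():
    """When the PC-PC pairs own the top correlations, their pool fraction is 1."""
    n = 20
    classes = np.array(["pc"] * 4 + ["nc"] * 16)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    rng = np.random.default_rng(5)
    vals = rng.uniform(0, 0.5, len(iu[0]))
    m[iu] = vals
    m = m + m.T
    np.fill_diagonal(m, 1.0)
    for i in range(4):            # 6 PC-PC pairs get the top values
        for j in range(i + 1, 4):
            m[i, j] = m[j, i] = 0.9 + 0.01 * (i + j)
    pool = sync_pool_composition(m, classes, percentile=95.0)
    assert pool["composition"]["pc|pc"] == pytest.approx(1.0)
    assert pool["pool_share"]["pc|pc"] > 0.5


def test_sync_pool_threshold_brute_force():
    """Pool membership equals an explicit sort of the upper triangle."""
    rng = np.random.default_rng(6)
    n = 10
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    classes = rng.choice(["a", "b"], n)
    pool = sync_pool_composition(m, classes, percentile=80.0)
    iu = np.triu_indices(n, 1)
    vals = m[iu]
    thr = np.percentile(vals, 80.0, method="midpoint")
    np.testing.assert_array_equal(pool["pool_mask"], vals > thr)


def test_sync_pool_size_near_five_percent():
    """Continuous values: ~5% of pairs sit above the 95th percentile."""
    rng = np.random.default_rng(7)
    n = 41                                    # 820 pairs -> expected 41 in pool
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    pool = sync_pool_composition(m, ["x"] * n, percentile=95.0)
    n_pairs = n * (n - 1) // 2
    assert abs(pool["pool_size"] - 0.05 * n_pairs) <= 1


def test_correlation_similarity_identities():
    rng = np.random.default_rng(8)
    A = rng.random((12, 12))
    A = (A + A.T) / 2
    assert correlation_similarity(A, A) == pytest.approx(1.0)
    B = -A.copy()
    assert correlation_similarity(A, B) == pytest.approx(-1.0)
    assert correlation_similarity(A, B) == correlation_similarity(B, A)


def test_correlation_similarity_null_is_small():
    rng = np.random.default_rng(9)
    hits = 0
    for _ in range(20):
        A = rng.normal(size=(50, 50))
        B = rng.normal(size=(50, 50))
        hits += abs(correlation_similarity((A + A.T) / 2, (B + B.T) / 2)) < 0.1
    assert hits >= 19


def test_phase_averaged_regression():
    rng = np.random.default_rng(10)
    base = rng.random((15, 15))
    base = (base + base.T) / 2
    corr = {"s1": base, "s2": base + rng.normal(0, 0.01, base.shape),
            "s3": base + rng.normal(0, 0.01, base.shape)}
    phases = {"s1": "healthy", "s2": "healthy", "s3": "early_post"}
    df = phase_averaged_pairwise(corr, phases)
    row = df.iloc[0]
    assert row["r"] > 0.99 and abs(row["slope"] - 1.0) < 0.05
    assert not row["excluded"]

    indep = {"s1": (lambda m: (m + m.T) / 2)(rng.normal(size=(15, 15))),
             "s3": (lambda m: (m + m.T) / 2)(rng.normal(size=(15, 15)))}
    df2 = phase_averaged_pairwise(indep, {"s1": "healthy", "s3": "early_post"})
    assert df2.iloc[0]["p"] > 0.001            # null: no systematic relation


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def test_field_rz_distances_and_categories(corridor):
    df = field_rz_geometry([30.0, 60.0, 90.0], corridor)
    assert df.loc[0, "distance_cm"] == 0 and df.loc[0, "category"] == "in"
    assert df.loc[1, "distance_cm"] == pytest.approx(10.0)
    assert df.loc[1, "category"] == "close"
    assert df.loc[2, "category"] == "far"      # 90 cm is 27 cm past RZ1's edge


def test_field_rz_stability_contrast(corridor):
    df = field_rz_geometry([60.0, 60.0], corridor,
                           classes=["stable_pc", "unstable_pc"])
    assert df.attrs["stability_contrast"] == pytest.approx(0.0)


def test_pair_euclidean_distance():
    cents = np.array([[0.0, 0.0], [3.0, 4.0], [0.0, 0.0]])
    corr = np.eye(3)
    res = pair_euclidean_distance(cents, corr)
    assert res["distance_um"][0] == pytest.approx(5.0)
    assert res["distance_um"][1] == pytest.approx(0.0)
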