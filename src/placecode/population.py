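"""Population-level structure: PVC curves, pairwise synchrony, RZ geometry.

The population vector correlation (PVC) between corridor positions x and y of
two sessions is the cosine of the across-neuron activity vectors,

    PVC(x, y) = Σ_j λ_j¹(x) λ_j²(y) / sqrt(Σ_j λ_j¹(x)² · Σ_j λ_j²(y)²),

summarised as a curve over the location offset Δx = |x − y| (0–275 cm). The
curve's y-intercept measures cross-session network stability, its maximum
absolute initial slope (0–100 cm) spatial precision, and the relative peak
prominence (RPP) of its local maxima the periodicity imposed by the regular
reward-zone layout.

Pairwise structure: Pearson correlations of ΔF/F traces ("pairwise firing
activity", synchrony in time) or of spatial maps ("spatial synchronicity"),
95th-percentile synchronous pools and their functional-class composition,
cosine similarity of off-diagonal correlation structure across days, and
phase-averaged pairwise-correlation regressions. Geometry helpers relate
place-field positions and ROI distances to the reward zones.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelextrema

from .corridor import CorridorConfig

__all__ = [
    "PVCResult",
    "pvc_matrix",
    "pvc_curve_stats",
    "rpp",
    "pairwise_correlations",
    "sync_pool_composition",
    "correlation_similarity",
    "phase_averaged_pairwise",
    "field_rz_geometry",
    "pair_euclidean_distance",
]


# ---------------------------------------------------------------------------
# population vector correlation
# ---------------------------------------------------------------------------

@dataclass
class PVCResult:
    matrix: np.ndarray        # bins × bins
    curve: np.ndarray         # offsets 0, 5, ..., 275 cm
    offsets_cm: np.ndarray
    y_intercept: float
    initial_slope: float      # correlation change per 100 cm
    rpp: list


def pvc_matrix(maps1: np.ndarray, maps2: np.ndarray) -> np.ndarray:
    """PVC(x, y) for all bin pairs of two sessions' map stacks.

    ``maps1``/``maps2`` are neurons × bins over the same tracked neurons.
    Positions whose population vector is all-zero get NaN entries. The
    statistic is scale-invariant: rescaling either session's maps by a
    positive constant leaves the matrix unchanged.
    """
    a = np.asarray(maps1, dtype=float)
    b = np.asarray(maps2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("map stacks must share neurons and bin count")
    num = a.T @ b                                   # bins × bins
    na = np.sqrt(np.einsum("jx,jx->x", a, a))
    nb = np.sqrt(np.einsum("jx,jx->x", b, b))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / np.outer(na, nb)
    out[na == 0, :] = np.nan
    out[:, nb == 0] = np.nan
    return out


def pvc_curve_stats(matrix: np.ndarray, config: CorridorConfig,
                    max_offset_cm: float = 275.0,
                    slope_window_cm: float = 100.0,
                    slope_scale_cm: float = 100.0) -> PVCResult:
    """Collapse a PVC matrix into its offset curve and summary metrics.

    curve(Δx) averages all (x, y) with |x − y| = Δx (missing entries
    skipped). The y-intercept is curve(0); the initial slope is the maximum
    absolute difference between consecutive offsets within 0–100 cm,
    expressed as correlation change per 100 cm.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    bs = config.bin_size_cm
    n_off = int(max_offset_cm / bs) + 1
    curve = np.full(n_off, np.nan)
    x, y = np.indices(m.shape)
    off = np.abs(x - y)
    for k in range(min(n_off, n)):
        vals = m[off == k]
        if np.any(~np.isnan(vals)):
            curve[k] = np.nanmean(vals)
    offsets = np.arange(n_off) * bs

    k_max = int(slope_window_cm / bs)
    diffs = np.abs(np.diff(curve[: k_max + 1]))
    slope = (float(np.nanmax(diffs)) * (slope_scale_cm / bs)
             if np.any(~np.isnan(diffs)) else np.nan)
    return PVCResult(matrix=m, curve=curve, offsets_cm=offsets,
                     y_intercept=float(curve[0]), initial_slope=slope,
                     rpp=rpp(curve))


def rpp(curve: np.ndarray) -> list:
    """Relative peak prominences of a PVC curve.

    Each interior local maximum is compared to the mean of its flanking
    local minima (curve endpoints count as valleys when no interior minimum
    intervenes): RPP = (peak − mean(valleys)) / peak. Monotone or flat
    curves have no peaks and return [].
    """
    c = np.asarray(curve, dtype=float)
    c = c[~np.isnan(c)]
    if len(c) < 5:
        raise ValueError("curve too short for periodicity analysis")
    peaks = argrelextrema(c, np.greater)[0]
    valleys = argrelextrema(c, np.less_equal)[0]
    out = []
    for p in peaks:
        left = valleys[valleys < p]
        right = valleys[valleys > p]
        lv = c[left.max()] if left.size else c[0]
        rv = c[right.min()] if right.size else c[-1]
        if c[p] != 0:
            out.append(float((c[p] - (lv + rv) / 2) / c[p]))
    return out


# ---------------------------------------------------------------------------
# pairwise correlation structure
# ---------------------------------------------------------------------------

def pairwise_correlations(series: np.ndarray) -> np.ndarray:
    """Symmetric Pearson correlation matrix across neurons.

    ``series`` is neurons × samples — ΔF/F traces over frames ("pairwise
    firing activity") or spatial maps over bins ("spatial synchronicity").
    Zero-variance rows get NaN rows/columns; the diagonal is 1 wherever
    defined.
    """
    s = np.asarray(series, dtype=float)
    if s.shape[0] < 2:
        raise ValueError("need at least 2 neurons")
    sd = s.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(s)
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    np.fill_diagonal(c, np.where(sd == 0, np.nan, 1.0))
    return c


def _upper_pairs(n: int):
    iu = np.triu_indices(n, k=1)
    return iu


def sync_pool_composition(matrix: np.ndarray, classes, percentile: float = 95.0):
    """Highly synchronous cell pairs and their class-pair composition.

    The pool holds the pairs whose correlation lies strictly above the given
    percentile of all off-diagonal upper-triangle values (midpoint
    interpolation). For each unordered class pair (e.g. PC–PC) the
    composition reports the fraction of that type's pairs that made the pool
    — under class labels independent of the correlations this converges to
    (100 − percentile)%. The share of the pool taken by each type is also
    returned (``pool_share``).
    """
    m = np.asarray(matrix, dtype=float)
    classes = np.asarray(classes)
    n = m.shape[0]
    if classes.shape[0] != n:
        raise ValueError("classes must cover all neurons")
    iu = _upper_pairs(n)
    vals = m[iu]
    ok = ~np.isnan(vals)
    if ok.sum() < 20:
        warnings.warn("fewer than 20 valid pairs: percentile threshold unstable")
    thr = np.percentile(vals[ok], percentile, method="midpoint")
    in_pool = ok & (vals > thr)

    pair_type = np.array(["|".join(sorted((str(a), str(b))))
                          for a, b in zip(classes[iu[0]], classes[iu[1]])])
    comp, share = {}, {}
    pool_size = int(in_pool.sum())
    for t in np.unique(pair_type):
        sel = (pair_type == t) & ok
        comp[t] = float(in_pool[sel].mean()) if sel.any() else np.nan
        share[t] = float((in_pool & sel).sum() / pool_size) if pool_size else np.nan
    return {"threshold": float(thr), "pool_mask": in_pool,
            "pairs": (iu[0], iu[1]), "composition": comp,
            "pool_share": share, "pool_size": pool_size}


def correlation_similarity(corrA: np.ndarray, corrB: np.ndarray) -> float:
    """Cosine similarity of two correlation matrices' strict upper triangles.

    Entries missing in either matrix are dropped pairwise; a zero-norm
    vector yields NaN. Symmetric in its arguments;
    ``correlation_similarity(A, A) == 1``.
    """
    A = np.asarray(corrA, dtype=float)
    B = np.asarray(corrB, dtype=float)
    if A.shape != B.shape:
        raise ValueError("matrices must share neuron ordering and size")
    iu = _upper_pairs(A.shape[0])
    a, b = A[iu], B[iu]
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0 or a.size == 0:
        return np.nan
    return float(np.dot(a, b) / (na * nb))


def phase_averaged_pairwise(trace_corr_by_session: dict, phase_of_session: dict,
                            p_threshold: float = 0.05) -> pd.DataFrame:
    """Regressions of phase-averaged pairwise correlations between phases.

    ``trace_corr_by_session`` maps session id -> neurons × neurons trace
    correlation matrix over the same tracked neurons (cells absent in any
    session of the compared phases must already be excluded). Pairwise
    coefficients are averaged across the sessions of each phase; for every
    phase pair the matched per-cell-pair values give a Pearson r, p-value
    and least-squares slope. Distributions whose correlation is not
    significant (p > 0.05) are flagged ``excluded``.
    """
    phases = {}
    for sid, m in trace_corr_by_session.items():
        phases.setdefault(phase_of_session[sid], []).append(np.asarray(m, float))
    if not phases:
        raise ValueError("no sessions supplied")
    means = {ph: np.nanmean(np.stack(ms), axis=0) for ph, ms in phases.items()}

    rows = []
    names = sorted(means)
    for i, p1 in enumerate(names):
        for p2 in names[i + 1:]:
            iu = _upper_pairs(means[p1].shape[0])
            a, b = means[p1][iu], means[p2][iu]
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 3:
                rows.append({"phase_a": p1, "phase_b": p2, "r": np.nan,
                             "p": np.nan, "slope": np.nan, "n_pairs": int(ok.sum()),
                             "excluded": True})
                continue
            res = stats.linregress(a[ok], b[ok])
            rows.append({
                "phase_a": p1, "phase_b": p2, "r": float(res.rvalue),
                "p": float(res.pvalue), "slope": float(res.slope),
                "n_pairs": int(ok.sum()),
                "excluded": bool(res.pvalue > p_threshold),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def field_rz_geometry(field_centers_cm, config: CorridorConfig,
                      classes=None, close_threshold_cm: float = 25.0) -> pd.DataFrame:
    """Distance of each place-field centre to the nearest reward zone.

    Distance is 0 inside a zone, else the gap to the nearest zone edge.
    Categories: ``in`` (0), ``close`` (0 < d ≤ threshold), ``far``
    (d > threshold). With class labels the frame also carries the
    stable-vs-unstable mean-distance contrast in ``attrs['stability_contrast']``
    (mean unstable distance − mean stable distance).
    """
    centers = np.atleast_1d(np.asarray(field_centers_cm, dtype=float))
    d = config.distance_to_rz(centers)
    cat = np.where(d == 0, "in", np.where(d <= close_threshold_cm, "close", "far"))
    df = pd.DataFrame({"center_cm": centers, "distance_cm": d, "category": cat})
    if classes is not None:
        df["class"] = np.asarray(classes)
        stable = df.loc[df["class"] == "stable_pc", "distance_cm"]
        unstable = df.loc[df["class"] == "unstable_pc", "distance_cm"]
        df.attrs["stability_contrast"] = (
            float(unstable.mean() - stable.mean())
            if len(stable) and len(unstable) else np.nan)
    return df


def pair_euclidean_distance(centroids_um: np.ndarray, corr_matrix: np.ndarray):
    """Pairwise ROI distances (µm) and their relation to synchrony.

    Returns the per-pair distances and correlations (upper triangle) plus the
    Pearson r between them — a flat relation indicates synchrony is not a
    mere neighbourhood effect.
    """
    c = np.asarray(centroids_um, dtype=float)
    m = np.asarray(corr_matrix, dtype=float)
    iu = _upper_pairs(c.shape[0])
    d = np.sqrt(((c[iu[0]] - c[iu[1]]) ** 2).sum(axis=1))
    r = m[iu]
    ok = ~np.isnan(r)
    rel = (float(np.corrcoef(d[ok], r[ok])[0, 1])
           if ok.sum() > 2 and d[ok].std() > 0 and r[ok].std() > 0 else np.nan)
    return {"distance_um": d, "correlation": r, "distance_synchrony_r": rel}
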