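"""Cross-session FOV alignment and nearest-neighbour ROI matching.

Chronic imaging revisits the same field of view on every session, but the
tissue shifts and deforms slightly over weeks. The FOV mean image is split
into patches (2×2 by default), the subpixel translation of each patch is
estimated by phase cross-correlation, and the patch shifts are interpolated
into a smooth per-pixel displacement field. ROI centroids of the first
session are displaced by the field and matched to the second session's
centroids by mutual nearest neighbours within a distance gate — an automatic
stand-in for the manual confirmation a human curator would perform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree
from skimage.registration import phase_cross_correlation

__all__ = ["ShiftField", "estimate_shift_field", "match_cells"]


@dataclass
class ShiftField:
    """Per-pixel 2-D displacement mapping session-A coordinates into B."""

    dy: np.ndarray   # rows × cols
    dx: np.ndarray

    def displace(self, points: np.ndarray) -> np.ndarray:
        """Apply the field to (row, col) centroid coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rows = np.clip(pts[:, 0], 0, self.dy.shape[0] - 1).astype(int)
        cols = np.clip(pts[:, 1], 0, self.dy.shape[1] - 1).astype(int)
        out = pts.copy()
        out[:, 0] += self.dy[rows, cols]
        out[:, 1] += self.dx[rows, cols]
        return out


def estimate_shift_field(fovA: np.ndarray, fovB: np.ndarray,
                         n_patches: int = 4, upsample_factor: int = 20) -> ShiftField:
    """Patchwise subpixel translation between two FOV images.

    The image is split into an n×n grid (n = sqrt(n_patches)); each patch's
    shift is estimated by FFT phase cross-correlation with subpixel
    upsampling, and the patch-centre estimates are interpolated (bilinear,
    edge-extended) to every pixel. A featureless (flat) patch carries no
    signal; its shift is replaced by the mean of the remaining patches.
    """
    A = np.asarray(fovA, dtype=float)
    B = np.asarray(fovB, dtype=float)
    if A.shape != B.shape:
        raise ValueError("FOV images must share dimensions")
    grid = int(round(np.sqrt(n_patches)))
    if grid * grid != n_patches:
        raise ValueError("n_patches must be a perfect square")
    H, W = A.shape
    ys = np.linspace(0, H, grid + 1).astype(int)
    xs = np.linspace(0, W, grid + 1).astype(int)

    shifts = np.full((grid, grid, 2), np.nan)
    centers_y = np.empty(grid)
    centers_x = np.empty(grid)
    for i in range(grid):
        centers_y[i] = (ys[i] + ys[i + 1]) / 2
        centers_x[i] = (xs[i] + xs[i + 1]) / 2
    for i in range(grid):
        for j in range(grid):
            pa = A[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
            pb = B[ys[i]:ys[i + 1], xs[j]:xs[j + 1]]
            if np.ptp(pa) == 0 or np.ptp(pb) == 0:
                continue
            # Hann window suppresses blob truncation at patch boundaries
            win = np.outer(np.hanning(pa.shape[0]), np.hanning(pa.shape[1]))
            shift, _, _ = phase_cross_correlation(
                (pa - pa.mean()) * win, (pb - pb.mean()) * win,
                upsample_factor=upsample_factor, normalization=None)
            shifts[i, j] = shift
    flat = np.isnan(shifts[..., 0])
    if flat.all():
        warnings.warn("all patches featureless: zero shift field")
        shifts[...] = 0.0
    elif flat.any():
        warnings.warn(f"{int(flat.sum())} featureless patch(es): shift set to mean of others")
        mean = np.nanmean(shifts.reshape(-1, 2), axis=0)
        shifts[flat] = mean

    # phase_cross_correlation returns the shift that registers B onto A;
    # the displacement of A's content into B is its negation
    shifts = -shifts

    yy, xx = np.mgrid[0:H, 0:W]
    # bilinear between patch centres, edge-extended beyond them: clipping the
    # query grid avoids amplifying per-patch noise by extrapolation
    qy = np.clip(yy.ravel(), centers_y.min(), centers_y.max())
    qx = np.clip(xx.ravel(), centers_x.min(), centers_x.max())
    pts = np.stack([qy, qx], axis=1)
    field = []
    for comp in range(2):
        interp = RegularGridInterpolator(
            (centers_y, centers_x), shifts[..., comp], method="linear")
        field.append(interp(pts).reshape(H, W))
    return ShiftField(dy=field[0], dx=field[1])


def match_cells(centroidsA: np.ndarray, centroidsB: np.ndarray,
                shift_field: ShiftField | None, max_dist_px: float = 12.0) -> pd.DataFrame:
    """Mutual-nearest-neighbour ROI matching after FOV alignment.

    Session-A centroids are displaced by the shift field (None = identity),
    then each is paired with its nearest session-B centroid via a k-d tree;
    a pair is accepted only when the relation is mutual and the residual
    distance is within ``max_dist_px``. Returns a table of
    (roi_A, roi_B, distance_px, accepted); each ROI appears in at most one
    accepted pair.
    """
    cA = np.atleast_2d(np.asarray(centroidsA, dtype=float))
    cB = np.atleast_2d(np.asarray(centroidsB, dtype=float))
    if cA.size == 0 or cB.size == 0:
        return pd.DataFrame(columns=["roi_A", "roi_B", "distance_px", "accepted"])
    moved = shift_field.displace(cA) if shift_field is not None else cA

    treeB = cKDTree(cB)
    dist_ab, nn_ab = treeB.query(moved)
    treeA = cKDTree(moved)
    _, nn_ba = treeA.query(cB)

    rows = []
    for a, (b, d) in enumerate(zip(nn_ab, dist_ab)):
        mutual = nn_ba[b] == a
        rows.append({"roi_A": a, "roi_B": int(b), "distance_px": float(d),
                     "accepted": bool(mutual and d <= max_dist_px)})
    return pd.DataFrame(rows)
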