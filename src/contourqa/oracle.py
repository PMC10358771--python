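"""Brute-force reference computations for the surface metrics.

Everything here is written for clarity and independence from the fast
paths in :mod:`contourqa.metrics`: surfaces are enumerated voxel by voxel
with explicit loops, nearest distances are exact all-pairs minima, and the
weighted percentile is re-derived from the cumulative distribution. These
routines are O(N^2) and only meant for small masks, where they define
correctness for the KD-tree-based implementations.
"""

from __future__ import annotations

import numpy as np

from .volume import BinaryMask

__all__ = [
    "brute_surface",
    "brute_slice_contour",
    "brute_directed_distances",
    "brute_mda",
    "brute_hd",
    "brute_sdsc",
    "brute_apl_slice2d",
]

_NEIGHBORS_3D = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


def brute_surface(mask: BinaryMask):
    """Exposed faces by explicit neighbour checks; returns (points, areas)."""
    m = np.asarray(mask.data, dtype=bool)
    dx, dy, dz = mask.spacing
    ox, oy, oz = mask.origin
    area_for = {0: dy * dz, 1: dx * dz, 2: dx * dy}
    pts, areas = [], []
    nx, ny, nz = m.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not m[i, j, k]:
                    continue
                for di, dj, dk in _NEIGHBORS_3D:
                    ni, nj, nk = i + di, j + dj, k + dk
                    outside = not (0 <= ni < nx and 0 <= nj < ny and 0 <= nk < nz)
                    if outside or not m[ni, nj, nk]:
                        axis = 0 if di else (1 if dj else 2)
                        center = [ox + i * dx, oy + j * dy, oz + k * dz]
                        center[axis] += 0.5 * (di + dj + dk) * mask.spacing[axis]
                        pts.append(center)
                        areas.append(area_for[axis])
    if not pts:
        return np.empty((0, 3)), np.empty((0,))
    return np.asarray(pts, dtype=np.float64), np.asarray(areas, dtype=np.float64)


def brute_slice_contour(slice_mask: np.ndarray, spacing, origin=(0.0, 0.0)):
    """In-plane contour edges of one 2D slice; returns (points, lengths)."""
    m = np.asarray(slice_mask, dtype=bool)
    dx, dy = float(spacing[0]), float(spacing[1])
    ox, oy = float(origin[0]), float(origin[1])
    pts, lens = [], []
    nx, ny = m.shape
    for i in range(nx):
        for j in range(ny):
            if not m[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                outside = not (0 <= ni < nx and 0 <= nj < ny)
                if outside or not m[ni, nj]:
                    cx = ox + i * dx + 0.5 * di * dx
                    cy = oy + j * dy + 0.5 * dj * dy
                    pts.append((cx, cy))
                    lens.append(dy if di else dx)
    if not pts:
        return np.empty((0, 2)), np.empty((0,))
    return np.asarray(pts, dtype=np.float64), np.asarray(lens, dtype=np.float64)


def brute_directed_distances(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """All-pairs nearest distance from each point of ``pa`` to ``pb``."""
    diff = pa[:, None, :] - pb[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)).min(axis=1)


def _brute_weighted_percentile(d: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(d)
    d, w = d[order], w[order]
    cum = np.cumsum(w)
    target = q / 100.0 * cum[-1]
    for i in range(len(d)):
        if cum[i] >= target - 1e-9:
            return float(d[i])
    return float(d[-1])


def brute_mda(auto: BinaryMask, ref: BinaryMask) -> float:
    pa, wa = brute_surface(auto)
    pr, wr = brute_surface(ref)
    d_ar = brute_directed_distances(pa, pr)
    d_ra = brute_directed_distances(pr, pa)
    num = (d_ar * wa).sum() + (d_ra * wr).sum()
    return float(num / (wa.sum() + wr.sum()))


def brute_hd(auto: BinaryMask, ref: BinaryMask, q: float = 95.0,
             convention: str = "directed_max") -> float:
    pa, wa = brute_surface(auto)
    pr, wr = brute_surface(ref)
    d_ar = brute_directed_distances(pa, pr)
    d_ra = brute_directed_distances(pr, pa)
    if convention == "pooled":
        return _brute_weighted_percentile(
            np.concatenate([d_ar, d_ra]), np.concatenate([wa, wr]), q)
    return max(_brute_weighted_percentile(d_ar, wa, q),
               _brute_weighted_percentile(d_ra, wr, q))


def brute_sdsc(auto: BinaryMask, ref: BinaryMask, tolerance_mm: float = 2.0) -> float:
    pa, wa = brute_surface(auto)
    pr, wr = brute_surface(ref)
    d_ar = brute_directed_distances(pa, pr)
    d_ra = brute_directed_distances(pr, pa)
    tol = tolerance_mm + 1e-9
    hit = wa[d_ar <= tol].sum() + wr[d_ra <= tol].sum()
    return float(hit / (wa.sum() + wr.sum()))


def brute_apl_slice2d(auto: BinaryMask, ref: BinaryMask,
                      tolerance_mm: float = 2.0) -> float:
    tol = tolerance_mm + 1e-9
    total = 0.0
    for z in range(ref.shape[2]):
        rs = ref.data[:, :, z]
        if not rs.any():
            continue
        pr, lr = brute_slice_contour(rs, ref.spacing[:2], ref.origin[:2])
        as_ = auto.data[:, :, z]
        if not as_.any():
            total += lr.sum()
            continue
        pa, _ = brute_slice_contour(as_, auto.spacing[:2], auto.origin[:2])
        d = brute_directed_distances(pr, pa)
        total += lr[d > tol].sum()
    return float(total)
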