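"""Independent oracles used by the test suite.

These deliberately use different algorithms from the package: box counting by
exhaustive per-box scanning, and triangle/cell intersection by
Sutherland–Hodgman polygon clipping against the six cell half-spaces (the
package uses a separating-axis test). Slow, but exact on small inputs.
"""

from __future__ import annotations

import numpy as np


def brute_force_box_count(occ: np.ndarray, size: int) -> int:
    """Count occupied boxes by explicitly scanning every box."""
    dims = occ.shape
    count = 0
    for i in range(0, dims[0], size):
        for j in range(0, dims[1], size):
            for k in range(0, dims[2], size):
                if occ[i : i + size, j : j + size, k : k + size].any():
                    count += 1
    return count


def _clip_halfspace(poly, dist_fn):
    """Keep the part of `poly` with dist_fn(p) <= 0 (closed half-space)."""
    out = []
    n = len(poly)
    for i in range(n):
        a, b = poly[i], poly[(i + 1) % n]
        da, db = dist_fn(a), dist_fn(b)
        if da <= 0:
            out.append(a)
        if (da < 0 < db) or (db < 0 < da):
            t = da / (da - db)
            out.append(a + t * (b - a))
    return out


def triangle_cell_intersects(tri: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> bool:
    """Closed-box triangle/cell intersection via polygon clipping."""
    poly = [tri[0].astype(float), tri[1].astype(float), tri[2].astype(float)]
    for axis in range(3):
        poly = _clip_halfspace(poly, lambda p, a=axis: lo[a] - p[a])
        if not poly:
            return False
        poly = _clip_halfspace(poly, lambda p, a=axis: p[a] - hi[a])
        if not poly:
            return False
    return True


def brute_force_voxelize(triangles: np.ndarray, origin: np.ndarray, h: float, n: int) -> np.ndarray:
    """Occupancy by clipping every triangle against every nearby cell.

    Candidate cells are taken one cell beyond each triangle's bounding box, so
    the geometric clip test — not index arithmetic — decides membership.
    """
    occ = np.zeros((n, n, n), dtype=bool)
    rel = triangles - origin
    for tri in rel:
        lo_idx = np.maximum(np.floor(tri.min(axis=0) / h).astype(int) - 1, 0)
        hi_idx = np.minimum(np.floor(tri.max(axis=0) / h).astype(int) + 1, n - 1)
        for i in range(lo_idx[0], hi_idx[0] + 1):
            for j in range(lo_idx[1], hi_idx[1] + 1):
                for k in range(lo_idx[2], hi_idx[2] + 1):
                    if occ[i, j, k]:
                        continue
                    lo = np.array([i, j, k]) * h
                    if triangle_cell_intersects(tri, lo, lo + h):
                        occ[i, j, k] = True
    return occ


def menger_sponge(level: int) -> np.ndarray:
    """Level-n Menger sponge occupancy on a 3**n cubic grid."""
    occ = np.ones((1, 1, 1), dtype=bool)
    for _ in range(level):
        n = occ.shape[0]
        new = np.zeros((3 * n,) * 3, dtype=bool)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    if (i == 1) + (j == 1) + (k == 1) >= 2:
                        continue
                    new[i * n : (i + 1) * n, j * n : (j + 1) * n, k * n : (k + 1) * n] = occ
        occ = new
    return occ


def random_triangle_mesh(rng: np.random.Generator, n_triangles: int, scale: float = 1.0):
    """Random triangle soup inside [0.1, 0.9]^3 * scale (generic coordinates)."""
    centers = rng.uniform(0.2 * scale, 0.8 * scale, size=(n_triangles, 1, 3))
    offsets = rng.uniform(-0.12 * scale, 0.12 * scale, size=(n_triangles, 3, 3))
    return (centers + offsets).reshape(-1, 3)
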