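"""Exact triangle–box overlap kernels (separating axis theorem), numba-compiled.

The test is the 13-axis SAT for a triangle against an axis-aligned cube: the 3
box face normals, the triangle plane normal, and the 9 cross products of
triangle edges with box axes. Cells are treated as closed boxes — exact contact
is overlap — with a relative slack of 1e-9 of the voxel edge in every
comparison so that triangles constructed to lie exactly on cell boundary
planes survive the floating-point division used to locate candidate cells.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["tri_box_overlap", "voxelize_triangles"]


@njit(cache=True)
def _axis_test(p0: float, p1: float, p2: float, rad: float, eps: float) -> bool:
    """True when the projections are separated on this axis."""
    lo = min(p0, min(p1, p2))
    hi = max(p0, max(p1, p2))
    return lo > rad + eps or hi < -rad - eps


@njit(cache=True)
def tri_box_overlap(v0, v1, v2, center, half, eps) -> bool:
    """Closed-box triangle/AABB overlap; `half` is the cube half edge."""
    # work in box-centred coordinates
    ax, ay, az = v0[0] - center[0], v0[1] - center[1], v0[2] - center[2]
    bx, by, bz = v1[0] - center[0], v1[1] - center[1], v1[2] - center[2]
    cx, cy, cz = v2[0] - center[0], v2[1] - center[1], v2[2] - center[2]

    # 1) box face normals (AABB overlap)
    if _axis_test(ax, bx, cx, half, eps):
        return False
    if _axis_test(ay, by, cy, half, eps):
        return False
    if _axis_test(az, bz, cz, half, eps):
        return False

    e0x, e0y, e0z = bx - ax, by - ay, bz - az
    e1x, e1y, e1z = cx - bx, cy - by, cz - bz
    e2x, e2y, e2z = ax - cx, ay - cy, az - cz

    # 2) nine cross-product axes, edge x box axis
    # e0
    if _axis_test(az * e0y - ay * e0z, bz * e0y - by * e0z, cz * e0y - cy * e0z,
                  half * (abs(e0y) + abs(e0z)), eps):
        return False
    if _axis_test(ax * e0z - az * e0x, bx * e0z - bz * e0x, cx * e0z - cz * e0x,
                  half * (abs(e0x) + abs(e0z)), eps):
        return False
    if _axis_test(ay * e0x - ax * e0y, by * e0x - bx * e0y, cy * e0x - cx * e0y,
                  half * (abs(e0x) + abs(e0y)), eps):
        return False
    # e1
    if _axis_test(az * e1y - ay * e1z, bz * e1y - by * e1z, cz * e1y - cy * e1z,
                  half * (abs(e1y) + abs(e1z)), eps):
        return False
    if _axis_test(ax * e1z - az * e1x, bx * e1z - bz * e1x, cx * e1z - cz * e1x,
                  half * (abs(e1x) + abs(e1z)), eps):
        return False
    if _axis_test(ay * e1x - ax * e1y, by * e1x - bx * e1y, cy * e1x - cx * e1y,
                  half * (abs(e1x) + abs(e1y)), eps):
        return False
    # e2
    if _axis_test(az * e2y - ay * e2z, bz * e2y - by * e2z, cz * e2y - cy * e2z,
                  half * (abs(e2y) + abs(e2z)), eps):
        return False
    if _axis_test(ax * e2z - az * e2x, bx * e2z - bz * e2x, cx * e2z - cz * e2x,
                  half * (abs(e2x) + abs(e2z)), eps):
        return False
    if _axis_test(ay * e2x - ax * e2y, by * e2x - bx * e2y, cy * e2x - cx * e2y,
                  half * (abs(e2x) + abs(e2y)), eps):
        return False

    # 3) triangle plane vs box
    nx = e0y * e1z - e0z * e1y
    ny = e0z * e1x - e0x * e1z
    nz = e0x * e1y - e0y * e1x
    d = -(nx * ax + ny * ay + nz * az)
    rad = half * (abs(nx) + abs(ny) + abs(nz))
    if d > rad + eps * (abs(nx) + abs(ny) + abs(nz) + 1.0):
        return False
    if d < -rad - eps * (abs(nx) + abs(ny) + abs(nz) + 1.0):
        return False
    return True


@njit(cache=True)
def _axis_range(tmin: float, tmax: float, h: float, n: int):
    """Candidate cell index range along one axis for triangle span [tmin, tmax].

    Coordinates are relative to the grid origin; cells are half-open
    [i*h, (i+1)*h) with boundary-touching contacts attributed to the
    lower-index cell. Returns (lo, hi, valid).
    """
    eps = 1e-9 * h
    flo = tmin / h
    fhi = tmax / h
    ilo = int(np.floor(flo))
    ihi = int(np.floor(fhi))
    if float(ihi) == fhi:  # upper span lies exactly on a cell boundary plane
        if tmax > tmin:
            ihi -= 1  # touch from below belongs to the cell under the plane
        else:
            ilo = ihi = ihi - 1  # degenerate span on a plane: lower cell
    if ihi < 0:
        if tmax >= -eps:
            ilo = 0
            ihi = 0
        else:
            return 0, -1, False  # entirely below the grid
    if ilo > n - 1:
        if tmin <= n * h + eps:
            ilo = n - 1
            ihi = n - 1
        else:
            return 0, -1, False  # entirely above the grid
    if ilo < 0:
        ilo = 0
    if ihi > n - 1:
        ihi = n - 1
    return ilo, ihi, True


@njit(cache=True)
def voxelize_triangles(tris, h, nx, ny, nz, occupancy):
    """Mark every cell whose closed cube intersects >= 1 triangle.

    `tris` is (m, 3, 3) float64 in grid coordinates (origin already
    subtracted); `occupancy` is a (nx, ny, nz) boolean array mutated in place.
    """
    eps = 1e-9 * h
    half = 0.5 * h
    center = np.empty(3)
    for t in range(tris.shape[0]):
        v0 = tris[t, 0]
        v1 = tris[t, 1]
        v2 = tris[t, 2]
        xlo, xhi, ok = _axis_range(
            min(v0[0], min(v1[0], v2[0])), max(v0[0], max(v1[0], v2[0])), h, nx
        )
        if not ok:
            continue
        ylo, yhi, ok = _axis_range(
            min(v0[1], min(v1[1], v2[1])), max(v0[1], max(v1[1], v2[1])), h, ny
        )
        if not ok:
            continue
        zlo, zhi, ok = _axis_range(
            min(v0[2], min(v1[2], v2[2])), max(v0[2], max(v1[2], v2[2])), h, nz
        )
        if not ok:
            continue
        for i in range(xlo, xhi + 1):
            center[0] = (i + 0.5) * h
            for j in range(ylo, yhi + 1):
                center[1] = (j + 0.5) * h
                for k in range(zlo, zhi + 1):
                    if occupancy[i, j, k]:
                        continue
                    center[2] = (k + 0.5) * h
                    if tri_box_overlap(v0, v1, v2, center, half, eps):
                        occupancy[i, j, k] = True
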