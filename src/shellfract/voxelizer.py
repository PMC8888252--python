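"""Surface voxelization: triangle mesh → binary 3D occupancy image.

This is the first stage of the fractal pipeline: the shell surface is rendered
into an isotropic cubic voxel grid (default 500³) and every cell whose closed
cube intersects at least one triangle is set. The voxelization is *surface*,
not solid: a closed shell produces a thin shell of occupied cells, which is
what makes the box-counting dimension land slightly above 2 for rough shell
surfaces instead of trending to 3 for filled volumes. The grid cube is sized
by the longest bounding-box axis (shorter axes are centred) so the same
nominal resolution applies regardless of shell aspect ratio, and a one-voxel
empty border (default) keeps occupied cells away from the grid boundary so box
counting never clips them.

Tie-break convention: cells are half-open ``[origin + i·h, origin + (i+1)·h)``
for indexing, and a triangle touching a cell boundary plane with no extent
across it is assigned to the lower-index cell (clamped into the grid at the
border). An axis-aligned unit cube inscribed in a 10³ grid therefore occupies
exactly the 10³ − 8³ = 488 boundary cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._overlap import voxelize_triangles
from .errors import GeometryError, ParameterError
from .mesh_io import TriangleMesh

__all__ = ["VoxelGrid", "voxelize_surface", "occupancy_count", "save_grid", "load_grid"]


@dataclass
class VoxelGrid:
    """A binary occupancy image with isotropic physical voxel size.

    ``origin`` is the physical position of the lower corner of voxel (0,0,0);
    ``voxel_size`` is the edge length of every voxel (one scalar serves all
    three axes).
    """

    occupancy: np.ndarray
    voxel_size: float
    origin: np.ndarray
    unit: str = "cm"
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.occupancy.ndim != 3:
            raise ParameterError("occupancy must be a 3D array")
        if not self.voxel_size > 0:
            raise ParameterError("voxel_size must be > 0")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(int(d) for d in self.occupancy.shape)


def voxelize_surface(
    mesh: TriangleMesh,
    resolution: int = 500,
    padding_voxels: int = 1,
    bounds: tuple | None = None,
) -> VoxelGrid:
    """Voxelize a triangle surface onto a cubic grid of side ``resolution``.

    Parameters
    ----------
    mesh : the surface to voxelize; must satisfy TriangleMesh invariants.
    resolution : voxels per axis (>= 8, default 500).
    padding_voxels : empty border kept on each side of the longest axis
        (default 1); the voxel size is ``max_extent / (resolution - 2*padding)``.
    bounds : optional ``(lower, upper)`` physical corners overriding the
        mesh-derived grid box; the voxel size is then the largest bounds
        extent divided by ``resolution`` and the grid is anchored at ``lower``.

    Returns a :class:`VoxelGrid` where a voxel is set iff its closed cell
    intersects at least one triangle (exact separating-axis test, with the
    boundary tie-break described in the module docstring).
    """
    if resolution < 8:
        raise ParameterError(f"resolution must be >= 8, got {resolution}")
    if padding_voxels < 0 or 2 * padding_voxels >= resolution:
        raise ParameterError(f"invalid padding_voxels {padding_voxels} for resolution {resolution}")
    mesh.validate()
    lo, hi = mesh.bbox()
    extent = hi - lo
    if np.all(extent == 0.0):
        raise GeometryError(f"mesh {mesh.id!r} bounding box is degenerate in all axes")

    if bounds is not None:
        blo = np.asarray(bounds[0], dtype=np.float64).reshape(3)
        bhi = np.asarray(bounds[1], dtype=np.float64).reshape(3)
        if np.any(bhi <= blo):
            raise ParameterError("bounds upper corner must exceed lower corner")
        h = float((bhi - blo).max()) / resolution
        origin = blo
    else:
        h = float(extent.max()) / (resolution - 2 * padding_voxels)
        # centre each axis inside the cube (equals bbox_min - padding·h on the
        # longest axis)
        origin = (lo + hi) / 2.0 - (resolution * h) / 2.0

    occupancy = np.zeros((resolution, resolution, resolution), dtype=bool)
    tris = np.ascontiguousarray(mesh.triangles() - origin, dtype=np.float64)
    voxelize_triangles(tris, h, resolution, resolution, resolution, occupancy)
    return VoxelGrid(
        occupancy=occupancy,
        voxel_size=h,
        origin=origin,
        unit=mesh.unit,
        specimen_id=mesh.id,
    )


def occupancy_count(grid: VoxelGrid) -> int:
    """Number of set voxels."""
    return int(np.count_nonzero(grid.occupancy))


def save_grid(grid: VoxelGrid, path: str | Path) -> Path:
    """Persist a grid as ``.npz`` (dims, packed occupancy bits, voxel size, origin)."""
    path = Path(path)
    np.savez_compressed(
        path,
        dims=np.asarray(grid.dims, dtype=np.int64),
        bits=np.packbits(grid.occupancy.reshape(-1)),
        voxel_size=np.float64(grid.voxel_size),
        origin=grid.origin,
        unit=np.str_(grid.unit),
        specimen_id=np.str_(grid.specimen_id),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_grid(path: str | Path) -> VoxelGrid:
    """Load a grid written by :func:`save_grid`."""
    with np.load(path) as data:
        dims = tuple(int(d) for d in data["dims"])
        n = dims[0] * dims[1] * dims[2]
        occupancy = np.unpackbits(data["bits"])[:n].astype(bool).reshape(dims)
        return VoxelGrid(
            occupancy=occupancy,
            voxel_size=float(data["voxel_size"]),
            origin=np.asarray(data["origin"], dtype=np.float64),
            unit=str(data["unit"]),
            specimen_id=str(data["specimen_id"]),
        )
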