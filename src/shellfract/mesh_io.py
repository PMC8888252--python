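"""STL triangle-mesh input/output with explicit physical units.

STL files carry no unit information, so every mesh is tagged with the unit the
caller asserts for it (default ``cm``, the scale at which a 0.055 cm box-size
threshold is meaningful for shells a few centimetres high). Both the binary
dialect (80-byte header, uint32 facet count, 50-byte little-endian facet
records) and the ASCII ``solid``/``facet normal``/``vertex`` grammar are read;
the dialect is auto-detected. Stored facet normals are ignored — occupancy
analyses downstream are orientation-free — and duplicate vertices are kept
exactly as found in the file (box counting is unaffected by vertex sharing; an
optional merge tolerance exists for watertightness checks only).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import EmptyMeshError, GeometryError, STLFormatError

__all__ = ["TriangleMesh", "MeshStats", "read_stl", "write_stl", "mesh_stats"]

_BINARY_FACET_DTYPE = np.dtype(
    [
        ("normal", "<f4", (3,)),
        ("v0", "<f4", (3,)),
        ("v1", "<f4", (3,)),
        ("v2", "<f4", (3,)),
        ("attr", "<u2"),
    ]
)

_VERTEX_RE = re.compile(rb"vertex\s+(\S+)\s+(\S+)\s+(\S+)")


@dataclass
class TriangleMesh:
    """A raw triangle surface with physical units.

    Parameters
    ----------
    vertices : (n, 3) float array, coordinates in ``unit``.
    faces : (m, 3) integer array of vertex indices.
    unit : physical length unit tag (default ``"cm"``).
    id : specimen identifier.
    """

    vertices: np.ndarray
    faces: np.ndarray
    unit: str = "cm"
    id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def triangles(self) -> np.ndarray:
        """Return the (m, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]

    def validate(self) -> None:
        """Check the structural invariants; raise a shellfract error otherwise."""
        if self.n_faces < 1:
            raise EmptyMeshError(f"mesh {self.id!r} has no faces")
        if not np.all(np.isfinite(self.vertices)):
            raise GeometryError(f"mesh {self.id!r} contains NaN/Inf coordinates")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=0) >= self.n_vertices:
            raise GeometryError(
                f"mesh {self.id!r} has face indices outside [0, {self.n_vertices})"
            )
        lo, hi = self.bbox()
        if int(np.count_nonzero(hi - lo > 0.0)) < 2:
            raise GeometryError(
                f"mesh {self.id!r} bounding box lacks positive extent in >= 2 axes"
            )


@dataclass
class MeshStats:
    """Descriptive statistics for a mesh; reported, never used to reject."""

    bbox_min: np.ndarray
    bbox_max: np.ndarray
    surface_area: float
    face_count: int
    is_watertight: bool
    degenerate_face_count: int

    def to_dict(self) -> dict:
        return {
            "bbox_min": [float(x) for x in self.bbox_min],
            "bbox_max": [float(x) for x in self.bbox_max],
            "surface_area": float(self.surface_area),
            "face_count": int(self.face_count),
            "is_watertight": bool(self.is_watertight),
            "degenerate_face_count": int(self.degenerate_face_count),
        }


def _read_binary(data: bytes, path: Path, unit: str, specimen_id: str) -> TriangleMesh:
    if len(data) < 84:
        raise STLFormatError(
            f"{path}: binary STL truncated at byte {len(data)} (need 84-byte preamble)"
        )
    (n_facets,) = np.frombuffer(data[80:84], dtype="<u4")
    expected = 84 + 50 * int(n_facets)
    if len(data) < expected:
        raise STLFormatError(
            f"{path}: binary STL truncated at byte {len(data)}; header promises "
            f"{int(n_facets)} facets = {expected} bytes"
        )
    if n_facets == 0:
        raise EmptyMeshError(f"{path}: STL contains zero triangles")
    records = np.frombuffer(data[84:expected], dtype=_BINARY_FACET_DTYPE)
    tri = np.stack(
        [records["v0"], records["v1"], records["v2"]], axis=1
    ).astype(np.float64)
    vertices = tri.reshape(-1, 3)
    faces = np.arange(vertices.shape[0], dtype=np.int64).reshape(-1, 3)
    return TriangleMesh(vertices, faces, unit=unit, id=specimen_id)


def _read_ascii(data: bytes, path: Path, unit: str, specimen_id: str) -> TriangleMesh:
    n_facet = data.count(b"facet normal")
    n_endfacet = data.count(b"endfacet")
    coords = []
    last_end = 0
    for m in _VERTEX_RE.finditer(data):
        try:
            coords.append([float(m.group(1)), float(m.group(2)), float(m.group(3))])
        except ValueError as exc:
            raise STLFormatError(
                f"{path}: unparsable vertex at byte {m.start()}: {exc}"
            ) from None
        last_end = m.end()
    if not coords:
        raise EmptyMeshError(f"{path}: STL contains zero triangles")
    if len(coords) % 3 != 0 or n_facet != n_endfacet or len(coords) != 3 * n_facet:
        raise STLFormatError(
            f"{path}: garbled ASCII STL near byte {last_end}: {n_facet} 'facet' / "
            f"{n_endfacet} 'endfacet' markers with {len(coords)} vertex lines"
        )
    vertices = np.asarray(coords, dtype=np.float64)
    faces = np.arange(vertices.shape[0], dtype=np.int64).reshape(-1, 3)
    return TriangleMesh(vertices, faces, unit=unit, id=specimen_id)


def read_stl(path: str | Path, unit: str = "cm", specimen_id: str | None = None) -> TriangleMesh:
    """Read an STL file (binary or ASCII, auto-detected).

    Faces are returned in file order, one vertex triplet per facet; stored
    normals are discarded. Truncated or garbled files raise
    :class:`~shellfract.errors.STLFormatError` naming the offending byte
    offset; a facet count of zero raises
    :class:`~shellfract.errors.EmptyMeshError`.
    """
    path = Path(path)
    data = path.read_bytes()
    if specimen_id is None:
        specimen_id = path.stem
    looks_ascii = data.lstrip()[:5] == b"solid" and (
        b"facet" in data or b"endsolid" in data
    )
    if looks_ascii and len(data) >= 84:
        # A binary file may start with "solid"; trust the binary length check.
        (n_facets,) = np.frombuffer(data[80:84], dtype="<u4")
        if len(data) == 84 + 50 * int(n_facets):
            looks_ascii = False
    if looks_ascii:
        mesh = _read_ascii(data, path, unit, specimen_id)
    else:
        mesh = _read_binary(data, path, unit, specimen_id)
    mesh.validate()
    return mesh


def write_stl(mesh: TriangleMesh, path: str | Path, binary: bool = True) -> Path:
    """Write a mesh as STL (binary by default). Coordinates are cast to float32."""
    path = Path(path)
    tri = mesh.triangles().astype(np.float32)
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    normals = np.cross(e1, e2)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        normals = np.where(norm > 0, normals / norm, 0.0).astype(np.float32)
    if binary:
        records = np.zeros(tri.shape[0], dtype=_BINARY_FACET_DTYPE)
        records["normal"] = normals
        records["v0"], records["v1"], records["v2"] = tri[:, 0], tri[:, 1], tri[:, 2]
        header = f"shellfract {mesh.id}".encode()[:80].ljust(80, b"\0")
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(np.uint32(tri.shape[0]).tobytes())
            fh.write(records.tobytes())
    else:
        lines = [f"solid {mesh.id}"]
        for n, t in zip(normals, tri):
            lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
            lines.append("    outer loop")
            for v in t:
                lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append(f"endsolid {mesh.id}\n")
        path.write_text("\n".join(lines))
    return path


def _merged_faces(mesh: TriangleMesh, tolerance: float) -> np.ndarray:
    """Reindex faces after snapping vertices to a `tolerance` grid."""
    keys = np.round(mesh.vertices / tolerance).astype(np.int64)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    return inverse[mesh.faces]


def mesh_stats(mesh: TriangleMesh, merge_tolerance: float = 0.0) -> MeshStats:
    """Compute descriptive statistics for a mesh.

    ``surface_area`` is the sum of triangle areas (unit²); watertightness means
    every undirected edge is shared by exactly two faces; a face is degenerate
    when its area is exactly zero. ``merge_tolerance`` > 0 snaps vertices to a
    grid of that spacing before the edge analysis, so meshes whose facets
    duplicate vertices (as STL does) can still be recognised as closed. The
    default 0 leaves vertices untouched.
    """
    tri = mesh.triangles()
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    faces = mesh.faces if merge_tolerance <= 0 else _merged_faces(mesh, merge_tolerance)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=faces, process=False)
    lo, hi = mesh.bbox()
    return MeshStats(
        bbox_min=lo,
        bbox_max=hi,
        surface_area=float(areas.sum()),
        face_count=mesh.n_faces,
        is_watertight=bool(tm.is_watertight),
        degenerate_face_count=int(np.count_nonzero(areas == 0.0)),
    )
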