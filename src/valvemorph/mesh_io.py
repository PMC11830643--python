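"""Valve mesh input/output and geometric primitives.

A valve mesh is an indexed triangle surface of a single bivalve shell valve,
in millimetres, pre-aligned to the study's axis convention:

* ``x`` — anterior–posterior axis (shell length),
* ``y`` — dorso-ventral axis (shell height),
* ``z`` — commissure-normal axis (single-valve half-width; the commissural
  plane is ``z = 0`` and the valve occupies ``z >= 0``).

Two roles are distinguished: a ``shell_solid`` is the closed, watertight
surface bounding the shell material of one valve; an ``interior_surface`` is
the open surface of the shell interior (the soft-tissue side), whose single
boundary loop lies in the commissural plane.

File reading and vertex welding are delegated to :mod:`trimesh`; the signed
tetrahedra volume sum — the primitive all volumetric metrics rest on — is
implemented here directly.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

__all__ = [
    "ValveMesh",
    "MeshValidityReport",
    "MeshFormatError",
    "EmptyMeshError",
    "DegenerateGeometryError",
    "read_mesh",
    "write_mesh",
    "validate_mesh",
    "mirror_valve",
    "signed_volume",
    "aligned_extents",
]

SHELL_SOLID = "shell_solid"
INTERIOR_SURFACE = "interior_surface"

#: Vertex-merge tolerance on load, as a fraction of the bounding-box diagonal.
MERGE_TOL_FRACTION = 1e-6

#: Triangles with area below this (mm^2) are dropped at load time.
DEGENERATE_AREA = 1e-12


class MeshFormatError(ValueError):
    """File could not be parsed as a supported mesh format (STL/OBJ/PLY)."""


class EmptyMeshError(ValueError):
    """Mesh contains no usable triangles."""


class DegenerateGeometryError(ValueError):
    """Mesh geometry is degenerate (e.g. fewer than 3 non-collinear points)."""


@dataclass(frozen=True)
class ValveMesh:
    """Indexed triangle surface of one valve.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex-index triples
    role : {"shell_solid", "interior_surface"}
    """

    vertices: np.ndarray
    faces: np.ndarray
    role: str = SHELL_SOLID
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Return the (m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                               process=False)

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, role: str = SHELL_SOLID,
                     **metadata) -> "ValveMesh":
        return cls(np.asarray(mesh.vertices, dtype=float),
                   np.asarray(mesh.faces, dtype=np.int64),
                   role=role, metadata=dict(metadata))


@dataclass(frozen=True)
class MeshValidityReport:
    """Exact combinatorial and metric properties of a loaded mesh."""

    closed: bool
    manifold: bool
    oriented: bool
    n_boundary_loops: int
    n_components: int
    total_area: float
    flagged: bool = False
    notes: tuple = ()


def _clean(vertices: np.ndarray, faces: np.ndarray):
    """Weld duplicate vertices (scale-free tolerance) and drop degenerate
    triangles.  Returns cleaned (vertices, faces)."""
    if len(faces) == 0:
        raise EmptyMeshError("mesh has no faces")
    mesh = trimesh.Trimesh(vertices, faces, process=False)
    extent = np.linalg.norm(mesh.bounds[1] - mesh.bounds[0])
    digits = None
    if extent > 0:
        # trimesh merges on rounded coordinates; convert the absolute
        # tolerance into a decimal-digit count
        digits = max(0, int(-np.floor(np.log10(MERGE_TOL_FRACTION * extent))))
    mesh.merge_vertices(digits_vertex=digits)
    areas = mesh.area_faces
    mesh.update_faces(areas > DEGENERATE_AREA)
    mesh.remove_unreferenced_vertices()
    if len(mesh.faces) == 0:
        raise EmptyMeshError("mesh is empty after degenerate-face cleaning")
    return (np.asarray(mesh.vertices, dtype=float),
            np.asarray(mesh.faces, dtype=np.int64))


def read_mesh(path, role: str = SHELL_SOLID) -> ValveMesh:
    """Read an STL (ASCII or binary), OBJ, or PLY file into a :class:`ValveMesh`.

    Duplicate vertices are merged within ``1e-6`` of the bounding-box
    diagonal, zero-area triangles are dropped, and face winding is made
    consistent where the connectivity permits.  Coordinates are taken as
    millimetres as stored.
    """
    try:
        loaded = trimesh.load(str(path), force="mesh", process=False)
    except EmptyMeshError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalise loader errors
        raise MeshFormatError(f"could not read mesh from {path!s}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise EmptyMeshError(f"no triangles found in {path!s}")
    vertices, faces = _clean(loaded.vertices, loaded.faces)
    mesh = trimesh.Trimesh(vertices, faces, process=False)
    if not mesh.is_winding_consistent:
        trimesh.repair.fix_winding(mesh)
    return ValveMesh(np.asarray(mesh.vertices, float),
                     np.asarray(mesh.faces, np.int64),
                     role=role, metadata={"source": str(path)})


def write_mesh(mesh: ValveMesh, path) -> None:
    """Write a mesh to STL/OBJ/PLY, dispatching on the file extension."""
    mesh.to_trimesh().export(str(path))


def _edge_counts(faces: np.ndarray):
    """Map each undirected edge to the list of (face, directed-edge) uses."""
    edges = defaultdict(list)
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            edges[key].append((fi, (u, v)))
    return edges


def _boundary_loops(edges) -> int:
    """Count closed loops formed by edges used by exactly one face."""
    boundary = [key for key, uses in edges.items() if len(uses) == 1]
    if not boundary:
        return 0
    adj = defaultdict(list)
    for u, v in boundary:
        adj[u].append(v)
        adj[v].append(u)
    seen = set()
    loops = 0
    for start in adj:
        if start in seen:
            continue
        loops += 1
        stack = [start]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(n for n in adj[node] if n not in seen)
    return loops


def validate_mesh(mesh: ValveMesh) -> MeshValidityReport:
    """Report closedness, manifoldness, orientation consistency, boundary
    loop count, connected components and total area.

    The booleans are exact properties of the face-edge incidence structure;
    nothing is repaired.  A ``shell_solid`` that is not closed+manifold, or a
    mesh with multiple connected components, is flagged for review.
    """
    tm = mesh.to_trimesh()
    edges = _edge_counts(mesh.faces)
    counts = np.array([len(uses) for uses in edges.values()])
    manifold = bool((counts <= 2).all())
    closed = bool((counts == 2).all())
    loops = _boundary_loops(edges)
    oriented = bool(tm.is_winding_consistent)
    n_components = int(tm.body_count)
    notes = []
    flagged = False
    if mesh.role == SHELL_SOLID and not (closed and manifold):
        flagged = True
        notes.append("shell_solid is not closed and 2-manifold")
    if n_components > 1:
        flagged = True
        notes.append(f"{n_components} connected components")
    return MeshValidityReport(closed=closed, manifold=manifold,
                              oriented=oriented, n_boundary_loops=loops,
                              n_components=n_components,
                              total_area=float(tm.area),
                              flagged=flagged, notes=tuple(notes))


def mirror_valve(mesh: ValveMesh) -> ValveMesh:
    """Reflect a valve across the commissural plane (``z -> -z``).

    Face winding is flipped so outward normals stay outward; every
    downstream metric of the mirrored valve equals that of the original.
    """
    vertices = mesh.vertices * np.array([1.0, 1.0, -1.0])
    faces = mesh.faces[:, ::-1]
    return replace(mesh, vertices=vertices, faces=faces)


def signed_volume(mesh: ValveMesh) -> float:
    """Sum of signed tetrahedra volumes across the surface mesh.

    Each triangle ``(v0, v1, v2)`` contributes ``v0 . (v1 x v2) / 6`` — the
    signed volume of the tetrahedron it spans with the origin.  For a closed,
    consistently outward-oriented mesh the sum is the exact enclosed volume;
    for an open mesh the value depends on the position of the origin.
    """
    tri = mesh.triangles()
    if len(tri) == 0:
        raise EmptyMeshError("cannot compute volume of an empty mesh")
    cross = np.cross(tri[:, 1], tri[:, 2])
    return float(np.einsum("ij,ij->i", tri[:, 0], cross).sum() / 6.0)


def aligned_extents(mesh: ValveMesh):
    """Axis-aligned bounding-box extents ``(length_x, height_y, halfwidth_z)``.

    The mesh must already sit in the standard axis convention, so the x
    extent is shell length, the y extent is shell height, and the z extent
    is the single-valve half-width.
    """
    v = mesh.vertices
    if len(v) < 3:
        raise DegenerateGeometryError("need at least 3 vertices")
    centered = v - v.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-12) < 2:
        raise DegenerateGeometryError("vertices are collinear")
    ext = v.max(axis=0) - v.min(axis=0)
    return float(ext[0]), float(ext[1]), float(ext[2])
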