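"""Morphological variables of a shell valve: pSV, SL and XS.

Three variables summarise each specimen:

* **pSV** (proportional shell volume) — shell-material volume divided by
  shell-material plus internal (soft tissue + water) volume, a proxy for
  the animal's investment in shell thickness and weight.  ``pSV =
  TSV / (TSV + TIV)`` where TSV and TIV are the total (both-valve) shell
  and internal volumes, each twice the single-valve value for these
  equivalve taxa.
* **SL** (shell length, mm) — bounding-box extent along the
  anterior–posterior axis.
* **XS** (cross-sectional aspect ratio) — shell width (doubled single-valve
  half-width) over shell height; 1 means as wide as tall.

The internal volume is measured from the open interior surface.  Two
closures of its boundary loop are provided: ``capped`` triangulates the
opening with a fan to the loop's own centroid (geometrically interpretable
as the cavity bounded by the interior surface and the commissural plane),
while ``origin_fan`` recentres the surface on its area-weighted centroid and
takes the raw signed-tetrahedra sum, which implicitly fans the opening to
that centroid.  On a unit hemisphere the two differ by exactly the cone
between the surface centroid and the boundary circle (2*pi/3 vs pi/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .mesh_io import (
    INTERIOR_SURFACE,
    ValveMesh,
    _edge_counts,
    aligned_extents,
    signed_volume,
    validate_mesh,
)

__all__ = [
    "ValveMetrics",
    "MeshNotClosedError",
    "AmbiguousOpeningError",
    "internal_volume",
    "compute_metrics",
]

DEFAULT_INTERNAL_MODE = "capped"
DEFAULT_LOG_BASE = 10.0


class MeshNotClosedError(ValueError):
    """A shell_solid failed the closed+manifold requirement; carries the
    validity report."""

    def __init__(self, report):
        self.report = report
        super().__init__(f"shell_solid mesh is not closed/manifold: {report}")


class AmbiguousOpeningError(ValueError):
    """Interior surface has more than one boundary loop."""


@dataclass(frozen=True)
class ValveMetrics:
    """Per-specimen morphometric variables (volumes in mm^3, lengths mm)."""

    valve_shell_volume: float
    valve_internal_volume: float
    TSV: float
    TIV: float
    pSV: float
    SL: float
    height: float
    width: float
    XS: float
    logSL: float
    internal_mode: str = DEFAULT_INTERNAL_MODE
    log_base: float = DEFAULT_LOG_BASE

    def as_dict(self) -> dict:
        return asdict(self)


def _boundary_loop_vertices(mesh: ValveMesh) -> list:
    """Vertex index sets of each open boundary loop."""
    edges = _edge_counts(mesh.faces)
    boundary = [key for key, uses in edges.items() if len(uses) == 1]
    if not boundary:
        return []
    from collections import defaultdict

    adj = defaultdict(set)
    for u, v in boundary:
        adj[u].add(v)
        adj[v].add(u)
    seen, loops = set(), []
    for start in adj:
        if start in seen:
            continue
        comp, stack = [], [start]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            comp.append(node)
            stack.extend(adj[node] - seen)
        loops.append(comp)
    return loops


def _area_weighted_centroid(mesh: ValveMesh) -> np.ndarray:
    tri = mesh.triangles()
    centers = tri.mean(axis=1)
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    return (centers * areas[:, None]).sum(axis=0) / areas.sum()


def internal_volume(interior: ValveMesh, mode: str = DEFAULT_INTERNAL_MODE) -> float:
    """Volume (mm^3) enclosed by an open interior surface.

    Parameters
    ----------
    interior : ValveMesh
        Surface of the shell interior with at most one open boundary loop.
    mode : {"capped", "origin_fan"}
        ``capped`` closes the boundary loop with a triangle fan to the loop
        centroid and returns the closed mesh's volume.  ``origin_fan``
        recentres the surface on its area-weighted centroid and returns the
        raw signed-tetrahedra sum (equivalent to fanning the opening to the
        centroid).  The absolute value is returned in both modes.
    """
    if mode not in ("capped", "origin_fan"):
        raise ValueError(f"unknown internal-volume mode: {mode!r}")
    loops = _boundary_loop_vertices(interior)
    if len(loops) > 1:
        raise AmbiguousOpeningError(
            f"interior surface has {len(loops)} boundary loops; expected 1")
    if not loops:
        if interior.role == INTERIOR_SURFACE:
            import warnings

            warnings.warn("interior_surface mesh is closed; treating as a "
                          "closed cavity", stacklevel=2)
        return abs(signed_volume(interior))

    if mode == "origin_fan":
        centroid = _area_weighted_centroid(interior)
        shifted = ValveMesh(interior.vertices - centroid, interior.faces,
                            role=interior.role)
        return abs(signed_volume(shifted))

    # capped: fan the single boundary loop to its own centroid
    loop = loops[0]
    loop_centroid = interior.vertices[loop].mean(axis=0)
    vertices = np.vstack([interior.vertices, loop_centroid[None, :]])
    apex = len(interior.vertices)
    # each boundary edge is traversed (u, v) by its single face; the cap
    # triangle traverses it (v, u) so the closed mesh winds consistently
    cap = []
    for uses in _edge_counts(interior.faces).values():
        if len(uses) == 1:
            _, (u, v) = uses[0]
            cap.append([v, u, apex])
    faces = np.vstack([interior.faces, np.asarray(cap, dtype=np.int64)])
    closed = ValveMesh(vertices, faces, role=interior.role)
    return abs(signed_volume(closed))


def compute_metrics(shell_solid: ValveMesh, interior: ValveMesh,
                    internal_mode: str = DEFAULT_INTERNAL_MODE,
                    log_base: float = DEFAULT_LOG_BASE) -> ValveMetrics:
    """Measure one specimen from its closed shell solid and interior surface.

    Raises :class:`MeshNotClosedError` (with the validity report attached)
    if the shell solid is not closed and 2-manifold.
    """
    report = validate_mesh(shell_solid)
    if not (report.closed and report.manifold):
        raise MeshNotClosedError(report)

    vsv = abs(signed_volume(shell_solid))
    viv = internal_volume(interior, mode=internal_mode)
    tsv, tiv = 2.0 * vsv, 2.0 * viv
    psv = tsv / (tsv + tiv)
    sl, height, halfwidth = aligned_extents(shell_solid)
    width = 2.0 * halfwidth
    xs = width / height
    log_sl = math.log(sl) / math.log(log_base)
    return ValveMetrics(valve_shell_volume=vsv, valve_internal_volume=viv,
                        TSV=tsv, TIV=tiv, pSV=psv, SL=sl, height=height,
                        width=width, XS=xs, logSL=log_sl,
                        internal_mode=internal_mode, log_base=log_base)
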