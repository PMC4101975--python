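"""Insertion trajectories and cochleostomy targets.

An ideal insertion trajectory is the line tangent to the smoothed ST
centerline at a chosen basal-turn angle ``theta_c``.  The cochleostomy
target is where that line, followed *outward* (against the insertion
direction, i.e. toward decreasing theta and out through the round-window
region of the promontory), first exits the labyrinth surface — found with
the Moller-Trumbore ray/triangle intersection algorithm, winding-agnostic
(no backface culling) so inconsistent face winding in segmented surfaces is
harmless.  For closed shells with inner and outer wall layers, the first
positive hit is the endosteal (inner) surface, matching the convention of
drilling to the endosteum.

Targets are swept over ``theta_c`` in steps of 2 deg up to 20 deg by
default; ``theta_c = 0`` (the round window itself) is excluded.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import List, Optional

import numpy as np

from .centerline import CenterlineSpline
from .errors import IntersectionError, PlanError
from .fileio import SurfaceMesh
from .frame import CochlearFrame

__all__ = [
    "RayHit",
    "InsertionTrajectory",
    "ray_triangle_intersect",
    "cast_to_surface",
    "plan_targets",
    "degenerate_triangle_count",
    "reset_degenerate_triangle_count",
]

#: minimum accepted ray parameter (mm); guards against self-hits at the anchor
T_EPS = 1e-9
#: determinant threshold below which a ray is treated as parallel to a triangle
_DET_EPS = 1e-12

_counters = {"degenerate_triangles": 0}


def degenerate_triangle_count() -> int:
    """Number of degenerate triangles encountered since the last reset."""
    return _counters["degenerate_triangles"]


def reset_degenerate_triangle_count() -> None:
    _counters["degenerate_triangles"] = 0


@dataclasses.dataclass(frozen=True)
class RayHit:
    t: float
    point: np.ndarray
    barycentric: np.ndarray


@dataclasses.dataclass(frozen=True)
class InsertionTrajectory:
    """Tangent trajectory at ``theta_c`` with its cochleostomy target.

    ``target = anchor - exit_distance * insertion_dir`` with
    ``exit_distance > 0``; the target lies on the hit triangle (barycentric
    coordinates in [0, 1] summing to 1).
    """

    theta_c: float
    anchor: np.ndarray
    insertion_dir: np.ndarray
    target: np.ndarray
    face_index: int
    exit_distance: float
    barycentric: Optional[np.ndarray] = None


def ray_triangle_intersect(origin, direction, triangle, t_eps: float = T_EPS):
    """Moller-Trumbore intersection of one ray with one triangle.

    Returns a :class:`RayHit` (smallest t > ``t_eps``) or ``None`` for a
    miss, a parallel ray, or a degenerate triangle (the latter also bumps
    the module's degenerate-triangle counter and emits a warning).
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    tri = np.asarray(triangle, dtype=float).reshape(3, 3)
    e1 = tri[1] - tri[0]
    e2 = tri[2] - tri[0]
    if np.linalg.norm(np.cross(e1, e2)) < 1e-12:
        _counters["degenerate_triangles"] += 1
        warnings.warn("degenerate (zero-area) triangle skipped", stacklevel=2)
        return None
    pvec = np.cross(d, e2)
    det = float(np.dot(e1, pvec))
    if abs(det) < _DET_EPS:
        return None  # ray parallel to the triangle plane
    inv_det = 1.0 / det
    tvec = o - tri[0]
    u = float(np.dot(tvec, pvec)) * inv_det
    if u < -1e-12 or u > 1.0 + 1e-12:
        return None
    qvec = np.cross(tvec, e1)
    v = float(np.dot(d, qvec)) * inv_det
    if v < -1e-12 or u + v > 1.0 + 1e-12:
        return None
    t = float(np.dot(e2, qvec)) * inv_det
    if t <= t_eps:
        return None
    bary = np.array([1.0 - u - v, u, v])
    return RayHit(t=t, point=o + t * d, barycentric=bary)


def _intersect_all(origin, direction, vertices, faces, t_eps: float = T_EPS):
    """Vectorized Moller-Trumbore of one ray against every triangle.

    Returns (t, bary) with ``t = inf`` where there is no valid hit.  This is
    an exhaustive all-triangles evaluation, so the nearest hit it yields *is*
    the brute-force nearest hit.
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0
    pvec = np.cross(np.broadcast_to(d, e2.shape), e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    degen = np.linalg.norm(np.cross(e1, e2), axis=1) < 1e-12
    ok = (np.abs(det) >= _DET_EPS) & ~degen
    inv_det = np.where(ok, 1.0 / np.where(det == 0.0, 1.0, det), 0.0)
    tvec = o - v0
    u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
    qvec = np.cross(tvec, e1)
    v = np.einsum("j,ij->i", d, qvec) * inv_det
    t = np.einsum("ij,ij->i", e2, qvec) * inv_det
    ok &= (u >= -1e-12) & (u <= 1.0 + 1e-12) & (v >= -1e-12) & (u + v <= 1.0 + 1e-12)
    ok &= t > t_eps
    t = np.where(ok, t, np.inf)
    bary = np.stack([1.0 - u - v, u, v], axis=1)
    return t, bary


def cast_to_surface(anchor, insertion_dir, mesh: SurfaceMesh, t_eps: float = T_EPS):
    """Cast the outward ray (along ``-insertion_dir``) and return the nearest hit.

    Returns ``(target, face_index, exit_distance, barycentric)``.  Raises
    :class:`IntersectionError` when the ray exits without hitting the surface.
    """
    a = np.asarray(anchor, dtype=float)
    d = np.asarray(insertion_dir, dtype=float)
    nd = np.linalg.norm(d)
    if nd < 1e-12:
        raise IntersectionError("insertion direction has zero length")
    outward = -d / nd
    t, bary = _intersect_all(a, outward, mesh.vertices, mesh.faces, t_eps)
    i = int(np.argmin(t))
    if not np.isfinite(t[i]):
        raise IntersectionError("trajectory does not exit through the surface")
    exit_distance = float(t[i])
    target = a + exit_distance * outward
    return target, i, exit_distance, bary[i]


def plan_targets(
    spline: CenterlineSpline,
    mesh: SurfaceMesh,
    frame: Optional[CochlearFrame] = None,
    theta_step: float = 2.0,
    theta_max: float = 20.0,
) -> List[InsertionTrajectory]:
    """Sweep theta_c over {theta_step, 2*theta_step, ..., theta_max}.

    The spline lives in the local cochlear frame; when ``frame`` is given the
    mesh is in world coordinates and the returned trajectories are expressed
    in world coordinates.  With ``frame=None`` the mesh must already share
    the spline's frame.  A theta_c whose outward ray misses the surface is
    skipped with a warning; an empty sweep raises :class:`PlanError`.
    """
    if theta_step <= 0 or theta_max < theta_step:
        raise PlanError(
            f"invalid sweep: theta_step={theta_step}, theta_max={theta_max}"
        )
    n = int(np.floor(theta_max / theta_step + 1e-9))
    grid = theta_step * np.arange(1, n + 1)
    lo, hi = spline.domain
    if lo > grid[0] + 1e-9 or hi < grid[-1] - 1e-9:
        raise PlanError(
            f"spline domain [{lo}, {hi}] deg does not cover the sweep "
            f"({grid[0]} to {grid[-1]} deg)"
        )
    plan: List[InsertionTrajectory] = []
    for theta_c in grid:
        anchor = spline.point(theta_c)
        direction = spline.tangent(theta_c)
        if frame is not None:
            anchor = frame.local_to_world(anchor)
            direction = frame.direction_to_world(direction)
        try:
            target, face, dist, bary = cast_to_surface(anchor, direction, mesh)
        except IntersectionError as exc:
            warnings.warn(f"theta_c = {theta_c:g} deg skipped: {exc}", stacklevel=2)
            continue
        plan.append(
            InsertionTrajectory(
                theta_c=float(theta_c),
                anchor=np.asarray(anchor, dtype=float),
                insertion_dir=np.asarray(direction, dtype=float) / np.linalg.norm(direction),
                target=target,
                face_index=face,
                exit_distance=dist,
                barycentric=bary,
            )
        )
    if not plan:
        raise PlanError("no theta_c in the sweep produced a surface exit")
    return plan
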