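"""Mesh, landmark and plan file I/O.

Meshes are triangle surfaces in mm (STL, PLY or OBJ; parsing delegated to
trimesh).  Landmarks and plans travel as JSON with world-frame coordinates in
mm; the landmark schema is ``{"R": [x,y,z], "C": ..., "A": ..., "I": ...,
"side": "left"|"right"|"auto"}`` and the plan schema is versioned (see
:func:`write_plan`).  Units are taken verbatim — no rescaling is performed.

Face winding is not normalized on read; downstream ray/triangle intersection
is winding-agnostic, since segmented-surface exports commonly have
inconsistent winding.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import trimesh

from .errors import LandmarkError, MeshError, MeshReadError, PlanError
from .frame import CochlearFrame, LandmarkSet

__all__ = [
    "SurfaceMesh",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "write_plan",
    "read_plan",
    "write_sections_csv",
]

PLAN_SCHEMA_VERSION = 1

_READ_FORMATS = ("stl", "ply", "obj")
_WRITE_FORMATS = ("stl", "stl_ascii", "ply", "obj")


@dataclasses.dataclass
class SurfaceMesh:
    """Triangulated surface: vertices (n, 3) in mm, faces (m, 3) 0-based.

    Zero-area (degenerate) triangles are flagged in ``n_degenerate_faces``
    but kept; the intersection code skips them.
    """

    vertices: np.ndarray
    faces: np.ndarray
    provenance: str = ""
    n_degenerate_faces: int = dataclasses.field(default=0, init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] == 0:
            raise MeshError(f"vertices must be (n, 3) with n > 0, got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] == 0:
            raise MeshError(f"faces must be (m, 3) with m > 0, got {f.shape}")
        if not np.all(np.isfinite(v)):
            raise MeshError("mesh has non-finite vertex coordinates")
        if f.min() < 0 or f.max() >= v.shape[0]:
            raise MeshError(
                f"face indices out of range [0, {v.shape[0] - 1}] "
                f"(min {f.min()}, max {f.max()})"
            )
        self.vertices = v
        self.faces = f
        tri = v[f]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        self.n_degenerate_faces = int(np.sum(areas < 1e-12))
        if self.n_degenerate_faces:
            warnings.warn(
                f"mesh {self.provenance!r} contains {self.n_degenerate_faces} "
                "zero-area faces (kept, skipped during intersection)",
                stacklevel=2,
            )

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


def _infer_format(path: Path, file_format: Optional[str]) -> str:
    if file_format is not None:
        fmt = file_format.lower()
    else:
        fmt = path.suffix.lstrip(".").lower()
    return fmt


def read_mesh(path, file_format: Optional[str] = None) -> SurfaceMesh:
    """Read an STL/PLY/OBJ triangle mesh (units taken as mm verbatim)."""
    path = Path(path)
    fmt = _infer_format(path, file_format)
    if fmt not in _READ_FORMATS:
        raise MeshReadError(f"unsupported mesh format {fmt!r}; expected one of {_READ_FORMATS}")
    if not path.exists():
        raise MeshReadError(f"mesh file not found: {path}")
    try:
        tm = trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:  # noqa: BLE001 - surface parse errors verbatim
        raise MeshReadError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshReadError(f"{path}: file contains no mesh geometry")
        tm = trimesh.util.concatenate(geoms)
    if tm.vertices.shape[0] == 0 or tm.faces.shape[0] == 0:
        raise MeshReadError(f"{path}: empty mesh (no vertices or faces)")
    if fmt == "stl":
        # STL is a triangle soup; merge duplicated corner vertices so that
        # cross-section centroids are not weighted by triangle valence.
        tm.merge_vertices()
    return SurfaceMesh(vertices=np.asarray(tm.vertices, dtype=float),
                       faces=np.asarray(tm.faces, dtype=np.int64),
                       provenance=str(path))


def write_mesh(mesh: SurfaceMesh, path, file_format: Optional[str] = None) -> None:
    """Write a mesh as ``stl`` (binary), ``stl_ascii``, ``ply`` or ``obj``."""
    path = Path(path)
    fmt = _infer_format(path, file_format)
    if fmt not in _WRITE_FORMATS:
        raise MeshError(f"unsupported output format {fmt!r}; expected one of {_WRITE_FORMATS}")
    tm = mesh.as_trimesh()
    data = tm.export(file_type=fmt)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def _landmark_point(obj: dict, key: str) -> list:
    if key not in obj:
        raise LandmarkError(f"landmark file is missing key {key!r}")
    val = obj[key]
    if not isinstance(val, (list, tuple)) or len(val) != 3:
        raise LandmarkError(f"landmark {key!r} must be a 3-array, got {val!r}")
    try:
        return [float(c) for c in val]
    except (TypeError, ValueError) as exc:
        raise LandmarkError(f"landmark {key!r} has a non-numeric entry: {val!r}") from exc


def read_landmarks(path) -> LandmarkSet:
    """Read a landmark JSON file; validates the LandmarkSet invariants."""
    path = Path(path)
    try:
        with open(path) as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise LandmarkError(f"failed to parse {path}: {exc}") from exc
    if not isinstance(obj, dict):
        raise LandmarkError(f"{path}: expected a JSON object at top level")
    side = obj.get("side", "auto")
    return LandmarkSet(
        R=_landmark_point(obj, "R"),
        C=_landmark_point(obj, "C"),
        A=_landmark_point(obj, "A"),
        I=_landmark_point(obj, "I"),
        side=side,
    )


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    obj = {
        "R": list(landmarks.R),
        "C": list(landmarks.C),
        "A": list(landmarks.A),
        "I": list(landmarks.I),
        "side": landmarks.side,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")


def _frame_to_json(frame: CochlearFrame) -> dict:
    return {
        "origin": list(frame.origin),
        "x_axis": list(frame.x_axis),
        "y_axis": list(frame.y_axis),
        "z_axis": list(frame.z_axis),
        "handedness": int(frame.handedness),
        "st_width_mm": float(frame.st_width),
    }


def _frame_from_json(obj: dict) -> CochlearFrame:
    rotation = np.vstack([obj["x_axis"], obj["y_axis"], obj["z_axis"]])
    return CochlearFrame(
        origin=np.asarray(obj["origin"], dtype=float),
        rotation=rotation,
        handedness=int(obj["handedness"]),
        st_width=float(obj["st_width_mm"]),
    )


def write_plan(path, plan: List, frame: CochlearFrame) -> None:
    """Write an insertion plan as versioned JSON (world-frame mm).

    Each trajectory record carries the cochleostomy angle ``theta_c`` (deg),
    the centerline anchor point, the unit insertion direction (toward
    increasing theta), the cochleostomy target on the mesh, the hit face
    index and the exit distance (mm).  JSON floats round-trip exactly at
    double precision.
    """
    if not plan:
        raise PlanError("nothing to write: empty plan")
    obj = {
        "schema_version": PLAN_SCHEMA_VERSION,
        "units": "mm",
        "frame": _frame_to_json(frame),
        "trajectories": [
            {
                "theta_c_deg": float(t.theta_c),
                "anchor": list(map(float, t.anchor)),
                "insertion_dir": list(map(float, t.insertion_dir)),
                "target": list(map(float, t.target)),
                "face_index": int(t.face_index),
                "exit_distance_mm": float(t.exit_distance),
            }
            for t in plan
        ],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")


def read_plan(path) -> Tuple[List, CochlearFrame]:
    """Read a plan JSON written by :func:`write_plan`."""
    from .planner import InsertionTrajectory  # local import to avoid a cycle

    path = Path(path)
    with open(path) as fh:
        obj = json.load(fh)
    version = obj.get("schema_version")
    if version != PLAN_SCHEMA_VERSION:
        raise PlanError(f"{path}: unsupported plan schema version {version!r}")
    frame = _frame_from_json(obj["frame"])
    plan = [
        InsertionTrajectory(
            theta_c=float(rec["theta_c_deg"]),
            anchor=np.asarray(rec["anchor"], dtype=float),
            insertion_dir=np.asarray(rec["insertion_dir"], dtype=float),
            target=np.asarray(rec["target"], dtype=float),
            face_index=int(rec["face_index"]),
            exit_distance=float(rec["exit_distance_mm"]),
        )
        for rec in obj["trajectories"]
    ]
    if not plan:
        raise PlanError(f"{path}: plan contains no trajectories")
    return plan, frame


def write_sections_csv(sections, path) -> None:
    """Export cross sections as CSV: theta_deg, n_points, n_removed_by_width, centroid."""
    import pandas as pd

    rows = [
        {
            "theta_deg": s.theta,
            "n_points": len(s.member_indices),
            "n_removed_by_width": s.n_removed_by_width,
            "centroid_x_mm": s.centroid[0],
            "centroid_y_mm": s.centroid[1],
            "centroid_z_mm": s.centroid[2],
        }
        for s in sections
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
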