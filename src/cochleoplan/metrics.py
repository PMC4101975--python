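"""Planning and accuracy evaluation metrics.

* ``alignment_angles`` — the two angular offsets used during interactive
  planning: the out-of-plane angle delta (trajectory dip relative to the
  assumed basilar-membrane plane) and the in-plane angle epsilon (deviation
  toward the lateral wall / modiolus).  Negative delta indicates basilar
  membrane collision risk; negative epsilon indicates modiolus collision
  risk.
* ``register_fiducials`` — least-squares proper rigid (Kabsch) registration
  of paired fiducial screw centers, reporting the RMS fiducial registration
  error (FRE).
* ``target_error`` — perpendicular distance from the planned cochleostomy
  target to the drilled trajectory axis.
* ``membrane_plane_error`` — mean |z| displacement between a measured
  membrane point set and the approximating x-y plane, profiled per angular
  bin and averaged over an angular window (default 45-60 deg, the region
  used for trajectory computation).
* ``angular_insertion_depth`` — unwrapped basal angle of the most apical
  electrode contact.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence, Tuple

import numpy as np

from .errors import EvaluationError, RegistrationError
from .frame import CochlearFrame, basal_angles

__all__ = [
    "AlignmentAngles",
    "RigidTransform",
    "MembraneErrorProfile",
    "alignment_angles",
    "register_fiducials",
    "target_error",
    "membrane_plane_error",
    "angular_insertion_depth",
]


@dataclasses.dataclass(frozen=True)
class AlignmentAngles:
    """Signed planning angles in degrees: delta out-of-plane, epsilon in-plane."""

    delta: float
    epsilon: float


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map ``p -> rotation @ p + translation`` with RMS FRE (mm)."""

    rotation: np.ndarray
    translation: np.ndarray
    fre: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_direction(self, directions: np.ndarray) -> np.ndarray:
        return np.asarray(directions, dtype=float) @ self.rotation.T

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(
            rotation=rot_inv, translation=-rot_inv @ self.translation, fre=self.fre
        )


def _unit(v, what: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).reshape(3)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise EvaluationError(f"{what} has zero length")
    return v / n


def alignment_angles(
    planned_dir, ideal_dir, frame: CochlearFrame, anchor
) -> AlignmentAngles:
    """Signed delta/epsilon offsets of a planned trajectory from the ideal.

    Both directions are world-frame unit vectors pointing along the insertion
    (toward increasing theta); ``anchor`` is the shared cochleostomy target
    in world coordinates.  In the local frame with u = ideal, v = planned:

    * ``delta = asin(u_z) - asin(v_z)`` — positive when the planned
      direction dips farther below the membrane plane (toward -z) than the
      ideal; negative delta means membrane collision risk.
    * ``epsilon`` is the signed angle in the x-y plane from the projected
      ideal tangent to the projected planned direction, positive toward the
      outward radial direction (lateral wall), negative toward the modiolus.
      The radial reference is orthonormalized against the projected tangent,
      so epsilon vanishes identically when planned == ideal.

    Raises :class:`EvaluationError` when the planned direction is (near)
    parallel to the modiolar axis, where the in-plane angle is undefined.
    """
    u = _unit(frame.direction_to_local(_unit(ideal_dir, "ideal direction")), "ideal direction")
    v = _unit(frame.direction_to_local(_unit(planned_dir, "planned direction")), "planned direction")
    a = frame.world_to_local(np.asarray(anchor, dtype=float).reshape(3))

    delta = np.degrees(
        np.arcsin(np.clip(u[2], -1.0, 1.0)) - np.arcsin(np.clip(v[2], -1.0, 1.0))
    )

    v_xy = v[:2]
    if np.linalg.norm(v_xy) < 1e-9:
        raise EvaluationError(
            "in-plane angle undefined: planned trajectory is parallel to the z-axis"
        )
    t_xy = u[:2]
    if np.linalg.norm(t_xy) < 1e-12:
        raise EvaluationError(
            "in-plane angle undefined: ideal trajectory is parallel to the z-axis"
        )
    t_hat = t_xy / np.linalg.norm(t_xy)
    r_xy = a[:2]
    if np.linalg.norm(r_xy) < 1e-9:
        raise EvaluationError("in-plane radial direction undefined: anchor on the z-axis")
    r_hat = r_xy / np.linalg.norm(r_xy)
    n_vec = r_hat - np.dot(r_hat, t_hat) * t_hat
    if np.linalg.norm(n_vec) < 1e-9:
        raise EvaluationError(
            "in-plane radial direction undefined: tangent is purely radial"
        )
    n_hat = n_vec / np.linalg.norm(n_vec)
    epsilon = np.degrees(np.arctan2(np.dot(v_xy, n_hat), np.dot(v_xy, t_hat)))
    return AlignmentAngles(delta=float(delta), epsilon=float(epsilon))


def register_fiducials(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid registration of paired points (Kabsch).

    ``moving`` and ``fixed`` are (n, 3) arrays with identical ordering,
    n >= 3 and not collinear.  No scaling, no reflection: the recovered
    rotation always has determinant +1.  FRE is the RMS residual after
    applying the transform to ``moving``.
    """
    m = np.asarray(moving, dtype=float).reshape(-1, 3)
    f = np.asarray(fixed, dtype=float).reshape(-1, 3)
    if m.shape != f.shape:
        raise RegistrationError(
            f"point lists differ in length: {m.shape[0]} vs {f.shape[0]}"
        )
    if m.shape[0] < 3:
        raise RegistrationError(f"need >= 3 fiducial pairs, got {m.shape[0]}")
    cm = m.mean(axis=0)
    cf = f.mean(axis=0)
    mc = m - cm
    fc = f - cf
    if np.linalg.matrix_rank(mc, tol=1e-9) < 2:
        raise RegistrationError("fiducials are collinear; rotation under-determined")
    h = mc.T @ fc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cf - rot @ cm
    resid = m @ rot.T + trans - f
    fre = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(rotation=rot, translation=trans, fre=fre)


def target_error(planned, axis_point, axis_dir) -> float:
    """Perpendicular distance (mm) from the planned target to the drilled axis.

    ``planned`` is an :class:`~cochleoplan.planner.InsertionTrajectory` or a
    bare 3-point; the drilled trajectory is the line through ``axis_point``
    with direction ``axis_dir``.
    """
    p = np.asarray(getattr(planned, "target", planned), dtype=float).reshape(3)
    a = np.asarray(axis_point, dtype=float).reshape(3)
    d = _unit(axis_dir, "drilled axis direction")
    w = p - a
    return float(np.linalg.norm(w - np.dot(w, d) * d))


@dataclasses.dataclass(frozen=True)
class MembraneErrorProfile:
    """Per-angular-bin mean |z| profile plus a window average (mm)."""

    bin_centers: np.ndarray
    bin_mean_abs_z: np.ndarray
    bin_counts: np.ndarray
    window: Tuple[float, float]
    window_mean: float


def membrane_plane_error(
    membrane_points_local: np.ndarray,
    theta_window: Tuple[float, float] = (45.0, 60.0),
    delta_theta: float = 5.0,
) -> MembraneErrorProfile:
    """Displacement of a membrane point set from the approximating x-y plane.

    Points are in the local cochlear frame; the profile reports the mean |z|
    per ``delta_theta`` bin over [0, 180] deg (empty bins omitted), and
    ``window_mean`` averages |z| over all points whose basal angle falls in
    ``theta_window`` (inclusive).
    """
    p = np.asarray(membrane_points_local, dtype=float).reshape(-1, 3)
    if p.shape[0] == 0:
        raise EvaluationError("membrane point set is empty")
    lo, hi = float(theta_window[0]), float(theta_window[1])
    if not (0.0 <= lo < hi <= 180.0):
        raise EvaluationError(f"theta window [{lo}, {hi}] must lie within [0, 180] deg")
    theta = basal_angles(p)
    absz = np.abs(p[:, 2])
    n_bins = int(round(180.0 / delta_theta))
    k = np.rint(theta / delta_theta).astype(int)
    centers, means, counts = [], [], []
    for kk in range(n_bins + 1):
        mask = k == kk
        if not np.any(mask):
            continue
        centers.append(kk * delta_theta)
        means.append(float(absz[mask].mean()))
        counts.append(int(np.count_nonzero(mask)))
    in_window = (theta >= lo) & (theta <= hi)
    if not np.any(in_window):
        raise EvaluationError(
            f"no membrane points in the window [{lo}, {hi}] deg"
        )
    return MembraneErrorProfile(
        bin_centers=np.asarray(centers, dtype=float),
        bin_mean_abs_z=np.asarray(means, dtype=float),
        bin_counts=np.asarray(counts, dtype=int),
        window=(lo, hi),
        window_mean=float(absz[in_window].mean()),
    )


def angular_insertion_depth(contact_points: Sequence, frame: CochlearFrame) -> float:
    """Unwrapped basal angle (deg) of the most apical electrode contact.

    Contacts must be ordered basal to apical (world coordinates).  Angles
    are unwrapped monotonically starting at the most basal contact, adding
    360 deg at each wrap; the depth is the unwrapped angle of the last
    contact.
    """
    pts = np.asarray(contact_points, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise EvaluationError("no electrode contacts supplied")
    theta = basal_angles(frame.world_to_local(pts))
    unwrapped = np.empty_like(theta)
    unwrapped[0] = theta[0]
    for i in range(1, theta.size):
        a = theta[i]
        while a < unwrapped[i - 1]:
            a += 360.0
        unwrapped[i] = a
    return float(unwrapped[-1])
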