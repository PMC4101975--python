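"""Anatomical landmarks and the local cochlear coordinate system.

The planning method anchors everything to four manually identified landmarks:

* ``R`` — center of the round window at the bony overhang,
* ``C`` — basal center of the modiolus (origin of the local frame),
* ``A`` — apical center of the modiolus,
* ``I`` — inner wall of the basal turn at the 0-degree reference angle.

The local frame places the origin at ``C``, the x-axis through ``R`` (which
defines the 0-degree basal-turn reference), and the z-axis along the modiolar
axis toward ``A``.  The x-y plane of this frame is the working approximation
of the basilar membrane: the scala tympani lies at positive y and negative z
in the basal half turn.  ``|R - I|`` is used as an upper bound on the scala
tympani width when filtering cross sections.

Because ``R`` and ``A`` are picked independently, the two requirements
"x through R" and "z through A" cannot both hold exactly; x is taken exact
(the 0-degree reference is the anchor of every downstream angle) and z is
Gram-Schmidt orthogonalized from ``A - C``.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Optional

import numpy as np

from .errors import FrameError, LandmarkError

__all__ = [
    "LandmarkSet",
    "CochlearFrame",
    "build_cochlear_frame",
    "basal_angle_of",
    "basal_angles",
]

#: minimum separation of R and A from C for a well-posed frame (mm)
MIN_LANDMARK_SEPARATION = 0.5
#: minimum angle between (R - C) and (A - C) (degrees)
MIN_AXIS_ANGLE = 10.0
#: hint points within this distance of R vote on the scala tympani side (mm)
HINT_RADIUS = 2.0


def _as_point(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise LandmarkError(f"landmark {name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise LandmarkError(f"landmark {name} has non-finite coordinates: {arr}")
    return arr


@dataclasses.dataclass(frozen=True)
class LandmarkSet:
    """The four anatomical landmarks, in world coordinates (mm).

    ``side`` is ``"left"``, ``"right"`` or ``"auto"``; with ``"auto"`` the
    ear side (and hence the sign of the local y-axis) is resolved from
    surface hint points at frame construction time.
    """

    R: np.ndarray
    C: np.ndarray
    A: np.ndarray
    I: np.ndarray
    side: str = "auto"

    def __post_init__(self) -> None:
        for name in ("R", "C", "A", "I"):
            object.__setattr__(self, name, _as_point(getattr(self, name), name))
        if self.side not in ("left", "right", "auto"):
            raise LandmarkError(f"side must be 'left', 'right' or 'auto', got {self.side!r}")
        rc = np.linalg.norm(self.R - self.C)
        ac = np.linalg.norm(self.A - self.C)
        if rc <= MIN_LANDMARK_SEPARATION:
            raise LandmarkError(
                f"|R - C| = {rc:.3g} mm <= {MIN_LANDMARK_SEPARATION} mm: "
                "R and C coincide or are too close (non-degenerate landmark invariant)"
            )
        if ac <= MIN_LANDMARK_SEPARATION:
            raise LandmarkError(
                f"|A - C| = {ac:.3g} mm <= {MIN_LANDMARK_SEPARATION} mm: "
                "A and C coincide or are too close (non-degenerate landmark invariant)"
            )
        cosang = float(np.dot(self.R - self.C, self.A - self.C) / (rc * ac))
        ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        if ang < MIN_AXIS_ANGLE or ang > 180.0 - MIN_AXIS_ANGLE:
            raise LandmarkError(
                f"angle between (R - C) and (A - C) is {ang:.2f} deg; "
                f"must lie in [{MIN_AXIS_ANGLE}, {180 - MIN_AXIS_ANGLE}] deg "
                "(axes-constructible invariant)"
            )
        if np.linalg.norm(self.R - self.I) <= 1e-9:
            raise LandmarkError("|R - I| = 0: scala tympani width parameter undefined")

    @property
    def st_width(self) -> float:
        """Assumed upper bound on the scala tympani width, ``|R - I|`` (mm)."""
        return float(np.linalg.norm(self.R - self.I))


@dataclasses.dataclass(frozen=True)
class CochlearFrame:
    """Orthonormal local cochlear coordinate system.

    ``rotation`` holds the local axes as *rows*, so for a world point ``p``
    the local coordinates are ``rotation @ (p - origin)``.  ``handedness`` is
    +1 for a right-handed axis triple (right ear convention) and -1 when the
    y-axis was flipped so the scala tympani lands at positive local y on a
    left ear; the rotation matrix then has determinant -1 but its inverse is
    still its transpose.
    """

    origin: np.ndarray
    rotation: np.ndarray
    handedness: int
    st_width: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        rot = self.rotation
        if rot.shape != (3, 3):
            raise FrameError(f"rotation must be 3x3, got {rot.shape}")
        if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-9):
            raise FrameError("frame axes are not orthonormal")
        det = float(np.linalg.det(rot))
        if abs(abs(det) - 1.0) > 1e-9:
            raise FrameError(f"|det(rotation)| = {abs(det):.12f} != 1")
        if self.handedness != int(np.sign(det)):
            raise FrameError("handedness does not match sign(det(rotation))")

    @property
    def x_axis(self) -> np.ndarray:
        return self.rotation[0]

    @property
    def y_axis(self) -> np.ndarray:
        return self.rotation[1]

    @property
    def z_axis(self) -> np.ndarray:
        return self.rotation[2]

    def world_to_local(self, points: np.ndarray) -> np.ndarray:
        """Map world points (..., 3) into the local frame."""
        p = np.asarray(points, dtype=float)
        return (p - self.origin) @ self.rotation.T

    def local_to_world(self, points: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`world_to_local` (exact; rotation is orthogonal)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation + self.origin

    def direction_to_local(self, directions: np.ndarray) -> np.ndarray:
        """Rotate world direction vectors into the local frame (no translation)."""
        return np.asarray(directions, dtype=float) @ self.rotation.T

    def direction_to_world(self, directions: np.ndarray) -> np.ndarray:
        return np.asarray(directions, dtype=float) @ self.rotation


def build_cochlear_frame(
    landmarks: LandmarkSet,
    st_hint_points: Optional[Iterable] = None,
) -> CochlearFrame:
    """Construct the local cochlear frame from the four landmarks.

    x = normalize(R - C) exactly; z = the component of (A - C) orthogonal to
    x, normalized (Gram-Schmidt); y = z x x (right-handed).  The y-axis sign
    is then resolved so the scala tympani sits at positive local y:

    * ``side == "right"`` — keep y (handedness +1);
    * ``side == "left"``  — flip y (handedness -1);
    * ``side == "auto"``  — require ``st_hint_points`` (labyrinth surface
      vertices); those within 2 mm of R vote, and y is flipped when fewer
      than half have positive local y.

    Raises :class:`LandmarkError` / :class:`FrameError` on degenerate input.
    """
    lm = landmarks
    x = lm.R - lm.C
    x = x / np.linalg.norm(x)
    w = lm.A - lm.C
    w_perp = w - np.dot(w, x) * x
    nw = np.linalg.norm(w_perp)
    if nw <= 1e-12:
        raise FrameError("A - C is parallel to R - C; z-axis undefined")
    z = w_perp / nw
    y = np.cross(z, x)

    if lm.side == "right":
        flip = False
    elif lm.side == "left":
        flip = True
    else:
        if st_hint_points is None:
            raise FrameError(
                "side is 'auto' but no st_hint_points were supplied; "
                "pass labyrinth surface points or set side explicitly"
            )
        hints = np.asarray(list(st_hint_points) if not isinstance(st_hint_points, np.ndarray) else st_hint_points, dtype=float)
        hints = hints.reshape(-1, 3)
        if hints.shape[0] == 0:
            raise FrameError(
                "side is 'auto' but st_hint_points is empty; set side explicitly"
            )
        near = hints[np.linalg.norm(hints - lm.R, axis=1) <= HINT_RADIUS]
        if near.shape[0] == 0:
            near = hints
        frac_pos = float(np.mean((near - lm.C) @ y > 0.0))
        flip = frac_pos < 0.5

    handedness = 1
    if flip:
        y = -y
        handedness = -1

    rotation = np.vstack([x, y, z])
    return CochlearFrame(
        origin=lm.C.copy(),
        rotation=rotation,
        handedness=handedness,
        st_width=lm.st_width,
    )


def basal_angles(points_local: np.ndarray) -> np.ndarray:
    """Basal-turn angle theta (degrees in [0, 360)) for local points (..., 3).

    theta is the in-plane angle from the +x axis (the round-window reference,
    theta = 0) toward +y, measured about the modiolar z-axis.
    """
    p = np.asarray(points_local, dtype=float)
    x, y = p[..., 0], p[..., 1]
    r2 = x * x + y * y
    if np.any(r2 <= 1e-24):
        raise FrameError("basal angle undefined for a point on the z-axis")
    theta = np.degrees(np.arctan2(y, x))
    return np.mod(theta, 360.0)


def basal_angle_of(point_local) -> float:
    """Basal-turn angle (degrees in [0, 360)) of a single local point."""
    return float(basal_angles(np.asarray(point_local, dtype=float).reshape(3)))
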