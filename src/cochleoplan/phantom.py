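"""Synthetic cochlear phantom with analytic ground truth.

The phantom is a helico-spiral tube standing in for the scala tympani (ST):
the centerline is ``c(theta) = (rho cos(theta), rho sin(theta), z(theta))``
with a logarithmic-spiral radius ``rho(theta) = a exp(-b theta)`` and a
height profile that keeps the basal half turn planar — the tube center sits
``center_depth * r`` *below* z = 0 for theta <= 180 deg and rises with a
constant pitch per turn thereafter.  This makes the phantom satisfy, exactly
at zero noise, the two geometric assumptions of the landmark-based planning
method: the basilar membrane lies in the x-y plane (the tube wall crosses
z = 0 along an analytic membrane locus), and the ST width equals
``|R - I| = 2 r``.

Landmarks are placed by construction: ``C`` at the origin, ``A`` on the
modiolar (z) axis above the apex, ``R`` at membrane level directly above
the centerline start (the round window sits at basilar-membrane level, the
lumen center below it), and ``I`` one tube diameter inward of ``R``.

The default mesh is the basal half-turn tube (theta in [0, 180] deg, capped
at both ends, watertight) — the segment the planning method actually uses.
Optional distractors emulate neighboring anatomy: a "vestibule" blob at
positive z (which the truncation rule must reject), a coplanar blob at
negative z several mm from the tube (which only the width filter can
reject), and the continuation of the spiral through the upper turns (whose
start dips slightly below the membrane plane near theta = 360 deg, the
hardest case for the width filter).  Gaussian vertex noise is reproducible
under a fixed seed.  The tube tapers linearly to ``taper`` times its basal
radius at the apex (default 0.5, emulating the apical narrowing of the
scala tympani).

``end_to_end_recovery`` runs the full pipeline (frame -> truncation ->
cross sections -> spline -> target sweep) against the analytic truth and
reports centerline, tangent and target-on-surface errors.
"""
from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Tuple

import numpy as np

from . import centerline as cl
from .errors import PhantomError
from .fileio import SurfaceMesh
from .frame import CochlearFrame, LandmarkSet, build_cochlear_frame
from .planner import InsertionTrajectory, plan_targets

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomResult",
    "RecoveryReport",
    "generate_phantom",
    "mirror_phantom",
    "end_to_end_recovery",
]

#: default radius decay (per degree): rho(360) = 0.6 * rho(0)
DEFAULT_RADIUS_DECAY = -math.log(0.6) / 360.0


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the spiral-tube phantom (lengths in mm, angles in deg)."""

    base_radius: float = 3.0
    radius_decay: float = DEFAULT_RADIUS_DECAY
    pitch: float = 1.8
    tube_radius: float = 0.6
    taper: float = 0.5
    turns: float = 2.5
    angular_resolution: float = 2.0
    circumferential_resolution: int = 24
    center_depth: float = 0.8
    noise_sd: float = 0.0
    include_distractors: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0 or self.tube_radius <= 0:
            raise PhantomError("base_radius and tube_radius must be positive")
        if not (0.0 < self.center_depth < 1.0):
            raise PhantomError(
                f"center_depth must be in (0, 1), got {self.center_depth}"
            )
        if self.turns < 0.5:
            raise PhantomError(f"turns must be >= 0.5, got {self.turns}")
        if self.angular_resolution <= 0 or self.circumferential_resolution < 8:
            raise PhantomError("mesh resolution too coarse")
        if self.taper <= 0:
            raise PhantomError(f"taper must be positive, got {self.taper}")
        if self.noise_sd < 0:
            raise PhantomError(f"noise_sd must be >= 0, got {self.noise_sd}")
        theta_max = 360.0 * self.turns
        theta = np.linspace(0.0, theta_max, 512)
        if np.any(self._radius(theta) >= self._rho(theta)):
            raise PhantomError(
                "tube radius reaches the spiral axis (r >= rho); phantom self-intersects"
            )

    @property
    def theta_max(self) -> float:
        return 360.0 * self.turns

    def _rho(self, theta) -> np.ndarray:
        return self.base_radius * np.exp(-self.radius_decay * np.asarray(theta, float))

    def _z(self, theta) -> np.ndarray:
        t = np.asarray(theta, dtype=float)
        base = -self.center_depth * self.tube_radius
        return np.where(t <= 180.0, base, base + self.pitch * (t - 180.0) / 360.0)

    def _radius(self, theta) -> np.ndarray:
        t = np.asarray(theta, dtype=float)
        return self.tube_radius * (1.0 + (self.taper - 1.0) * t / self.theta_max)


def _centerline(spec: PhantomSpec, theta) -> np.ndarray:
    t = np.asarray(theta, dtype=float)
    phi = np.radians(t)
    rho = spec._rho(t)
    return np.stack([rho * np.cos(phi), rho * np.sin(phi), spec._z(t)], axis=-1)


def _tangent(spec: PhantomSpec, theta) -> np.ndarray:
    t = np.asarray(theta, dtype=float)
    phi = np.radians(t)
    rho = spec._rho(t)
    drho = -spec.radius_decay * rho  # d(rho)/d(theta), theta in degrees
    k = math.pi / 180.0
    dx = drho * np.cos(phi) - rho * np.sin(phi) * k
    dy = drho * np.sin(phi) + rho * np.cos(phi) * k
    dz = np.where(t <= 180.0, 0.0, spec.pitch / 360.0) * np.ones_like(t)
    d = np.stack([dx, dy, dz], axis=-1)
    return d / np.linalg.norm(d, axis=-1, keepdims=True)


@dataclasses.dataclass
class PhantomTruth:
    """Analytic ground truth attached to a generated phantom."""

    spec: PhantomSpec
    membrane_points: np.ndarray
    st_membership: np.ndarray
    vertex_theta: np.ndarray
    mirror: bool = False

    def _m(self, pts: np.ndarray) -> np.ndarray:
        if self.mirror:
            pts = pts * np.array([1.0, -1.0, 1.0])
        return pts

    def centerline(self, theta) -> np.ndarray:
        """Analytic tube centerline at theta (deg), world coordinates."""
        return self._m(_centerline(self.spec, theta))

    def tangent(self, theta) -> np.ndarray:
        """Analytic unit tangent toward increasing theta, world coordinates."""
        return self._m(_tangent(self.spec, theta))

    def tube_radius_at(self, theta) -> np.ndarray:
        return self.spec._radius(theta)

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned distance from points to the analytic basal tube surface.

        Considers the tube wall over the basal half turn (|distance to
        centerline - local radius|) and the two flat end caps at 0 and
        180 deg.
        """
        p = self._m(np.atleast_2d(np.asarray(points, dtype=float)))
        spec = self.spec
        lo = 0.5 * spec.angular_resolution
        hi = 180.0 - 0.5 * spec.angular_resolution
        grid = np.arange(lo, hi + 0.05, 0.05)
        cpts = _centerline(spec, grid)
        radii = spec._radius(grid)
        out = np.empty(p.shape[0])
        for i, q in enumerate(p):
            d = np.linalg.norm(cpts - q, axis=1)
            j = int(np.argmin(d))
            wall = abs(d[j] - radii[j])
            cap = min(
                self._cap_distance(q, lo),
                self._cap_distance(q, hi),
            )
            out[i] = min(wall, cap)
        return out

    def _cap_distance(self, q: np.ndarray, theta_end: float) -> float:
        spec = self.spec
        c0 = _centerline(spec, theta_end).reshape(3)
        t0 = _tangent(spec, theta_end).reshape(3)
        r0 = float(spec._radius(theta_end))
        w = q - c0
        axial = float(np.dot(w, t0))
        radial = float(np.linalg.norm(w - axial * t0))
        if radial <= r0:
            return abs(axial)
        return math.hypot(axial, radial - r0)


@dataclasses.dataclass
class PhantomResult:
    mesh: SurfaceMesh
    landmarks: LandmarkSet
    truth: PhantomTruth
    spec: PhantomSpec


def _tube_frames(spec: PhantomSpec, thetas: np.ndarray):
    """(outward-radial, vertical) frame of the radial plane at each theta.

    Tube rings are drawn in the radial half-planes through the z-axis — the
    same planes the downstream cross-section binning samples — so all
    vertices of a ring share exactly one basal angle and lie exactly at
    distance r from the ring's centerline point.  (Relative to sections
    perpendicular to the tangent this widens the tube by a factor
    1/cos(pitch angle), well under 1% here.)
    """
    phi = np.radians(np.asarray(thetas, dtype=float))
    zeros = np.zeros_like(phi)
    n1 = np.stack([np.cos(phi), np.sin(phi), zeros], axis=1)
    n2 = np.stack([zeros, zeros, np.ones_like(phi)], axis=1)
    return n1, n2


def _tube_segment(spec: PhantomSpec, theta_start: float, theta_end: float):
    """Mesh one capped tube segment; returns (vertices, faces, vertex_theta).

    Rings sit at half-step offsets (theta_start + res/2, + 3 res/2, ...), so
    no vertex lies exactly on the y = 0 truncation plane at 0 or 180 deg —
    plane-sitting vertices would make the truncation rule numerically
    unstable under rigid transforms of the whole phantom.
    """
    thetas = np.arange(theta_start + 0.5 * spec.angular_resolution, theta_end,
                       spec.angular_resolution)
    m = spec.circumferential_resolution
    psi = np.radians(np.arange(m) * 360.0 / m)

    cpts = _centerline(spec, thetas)
    radii = spec._radius(thetas)
    n1, n2 = _tube_frames(spec, thetas)

    # complete rings of identical circumferential phase: each ring then
    # contributes a deterministic mean, keeping cross-section centroids free
    # of circumferential sampling noise
    ring_offsets = (
        np.cos(psi)[None, :, None] * n1[:, None, :]
        + np.sin(psi)[None, :, None] * n2[:, None, :]
    )
    verts = cpts[:, None, :] + radii[:, None, None] * ring_offsets
    n_rings = len(thetas)
    vertices = verts.reshape(-1, 3)
    vertex_theta = np.repeat(thetas, m)

    faces: List[Tuple[int, int, int]] = []
    for i in range(n_rings - 1):
        for j in range(m):
            a = i * m + j
            b = i * m + (j + 1) % m
            c = (i + 1) * m + j
            d = (i + 1) * m + (j + 1) % m
            faces.append((a, b, c))
            faces.append((b, d, c))
    # end caps (fans around the centerline end points)
    cap0 = len(vertices)
    cap1 = cap0 + 1
    vertices = np.vstack([vertices, cpts[0], cpts[-1]])
    vertex_theta = np.append(vertex_theta, [np.nan, np.nan])
    for j in range(m):
        faces.append((cap0, (j + 1) % m, j))
        base = (n_rings - 1) * m
        faces.append((cap1, base + j, base + (j + 1) % m))
    return vertices, np.asarray(faces, dtype=np.int64), vertex_theta


def generate_phantom(spec: PhantomSpec) -> PhantomResult:
    """Generate the phantom mesh, landmarks and analytic truth.

    The default mesh is the capped basal half-turn tube and is watertight at
    zero noise.  ``include_distractors`` appends the spiral continuation
    (theta from 180 deg to ``360 * turns``), a vestibule blob above the
    membrane plane and a coplanar far blob.  Vertices are unique (indexed
    rings, no triangle soup); the same spec (including seed) yields
    byte-identical output.
    """
    vertices, faces_arr, vertex_theta = _tube_segment(spec, 0.0, 180.0)
    faces: List[Tuple[int, int, int]] = [tuple(f) for f in faces_arr]
    basal_cap_indices = (len(vertices) - 2, len(vertices) - 1)

    if spec.include_distractors:
        import trimesh

        parts = []
        if spec.theta_max > 180.0 + spec.angular_resolution:
            parts.append(_tube_segment(spec, 180.0, spec.theta_max))
        vestibule = trimesh.creation.icosphere(subdivisions=2, radius=1.2)
        vestibule.apply_translation(
            [spec.base_radius + 0.5, 1.0, 1.5 + spec.tube_radius]
        )
        coplanar = trimesh.creation.icosphere(subdivisions=1, radius=0.5)
        rho90 = float(spec._rho(90.0))
        coplanar.apply_translation([0.0, rho90 + 5.0, -0.5])
        for blob in (vestibule, coplanar):
            parts.append(
                (
                    np.asarray(blob.vertices, dtype=float),
                    np.asarray(blob.faces, dtype=np.int64),
                    np.full(len(blob.vertices), np.nan),
                )
            )
        for pv, pf, pt in parts:
            offset = len(vertices)
            vertices = np.vstack([vertices, pv])
            vertex_theta = np.append(vertex_theta, pt)
            faces.extend((pf + offset).tolist())

    faces_arr = np.asarray(faces, dtype=np.int64)

    # analytic ST membership (noiseless coordinates): basal tube below the
    # membrane plane in the first half turn
    with np.errstate(invalid="ignore"):
        basal = vertex_theta <= 180.0  # nan (caps, distractors) -> False
    basal[list(basal_cap_indices)] = True  # the basal tube's own cap centers
    st_membership = basal & (vertices[:, 1] > 0.0) & (vertices[:, 2] < 0.0)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vertices = vertices + rng.normal(0.0, spec.noise_sd, vertices.shape)

    mesh = SurfaceMesh(
        vertices=vertices,
        faces=faces_arr,
        provenance=f"phantom(seed={spec.seed})",
    )

    rho0 = float(spec._rho(0.0))
    landmarks = LandmarkSet(
        R=np.array([rho0, 0.0, 0.0]),
        C=np.zeros(3),
        A=np.array([0.0, 0.0, max(3.0, float(spec._z(spec.theta_max)) + 2.0 * spec.tube_radius)]),
        I=np.array([rho0 - 2.0 * spec.tube_radius, 0.0, 0.0]),
        side="right",
    )

    # membrane: analytic locus where the basal tube wall crosses z = 0
    basal_thetas = np.arange(0.0, 180.0 + 1e-9, spec.angular_resolution)
    c_b = _centerline(spec, basal_thetas)
    r_b = spec._radius(basal_thetas)
    n1_b, n2_b = _tube_frames(spec, basal_thetas)
    s = np.clip(spec.center_depth * spec.tube_radius / r_b, -1.0, 1.0)
    cos_psi = np.sqrt(1.0 - s**2)
    membrane = np.concatenate(
        [
            c_b + r_b[:, None] * (sign * cos_psi[:, None] * n1_b + s[:, None] * n2_b)
            for sign in (+1.0, -1.0)
        ]
    )

    truth = PhantomTruth(
        spec=spec,
        membrane_points=membrane,
        st_membership=st_membership,
        vertex_theta=vertex_theta,
    )
    return PhantomResult(mesh=mesh, landmarks=landmarks, truth=truth, spec=spec)


_MIRROR = np.array([1.0, -1.0, 1.0])


def mirror_phantom(result: PhantomResult) -> PhantomResult:
    """Mirror a phantom across the x-z plane (right ear -> left ear).

    Landmark side flips; the analytic truth is mirrored consistently.
    """
    mesh = SurfaceMesh(
        vertices=result.mesh.vertices * _MIRROR,
        faces=result.mesh.faces.copy(),
        provenance=result.mesh.provenance + " (mirrored)",
    )
    lm = result.landmarks
    landmarks = LandmarkSet(
        R=lm.R * _MIRROR,
        C=lm.C * _MIRROR,
        A=lm.A * _MIRROR,
        I=lm.I * _MIRROR,
        side="left" if lm.side == "right" else "right",
    )
    truth = PhantomTruth(
        spec=result.spec,
        membrane_points=result.truth.membrane_points * _MIRROR,
        st_membership=result.truth.st_membership.copy(),
        vertex_theta=result.truth.vertex_theta.copy(),
        mirror=not result.truth.mirror,
    )
    return PhantomResult(mesh=mesh, landmarks=landmarks, truth=truth, spec=result.spec)


@dataclasses.dataclass
class RecoveryReport:
    """Full-pipeline recovery errors against the analytic phantom truth."""

    n_vertices: int
    n_truncated: int
    n_sections: int
    centerline_mean_error: float
    centerline_max_error: float
    tangent_max_error_deg: float
    target_surface_max_residual: float
    n_trajectories: int
    frame: CochlearFrame
    spline: cl.CenterlineSpline
    sections: list
    plan: List[InsertionTrajectory]
    phantom: PhantomResult


def end_to_end_recovery(
    spec: PhantomSpec,
    phantom: Optional[PhantomResult] = None,
    delta_theta: float = 5.0,
    residual_tol: float = 0.05,
    theta_step: float = 2.0,
    theta_max: float = 20.0,
) -> RecoveryReport:
    """Run the full planning pipeline on a phantom and score it against truth.

    Pipeline: build the cochlear frame from the constructed landmarks,
    truncate to the basal ST, bin radial cross sections (width-filtered),
    fit the centerline spline, and sweep cochleostomy targets.  Errors:

    * centerline mean/max distance (mm) between the fitted spline and the
      analytic centerline, sampled every 1 deg over the spline domain;
    * maximum angular deviation (deg) between fitted and analytic tangents
      over the cochleostomy sweep angles;
    * maximum distance (mm) from any cochleostomy target to the analytic
      phantom surface.
    """
    result = phantom if phantom is not None else generate_phantom(spec)
    frame = build_cochlear_frame(result.landmarks, st_hint_points=result.mesh.vertices)
    verts_local = frame.world_to_local(result.mesh.vertices)
    truncated = cl.truncate_to_basal_st(verts_local)
    sections = cl.bin_cross_sections(
        truncated, st_width=frame.st_width, delta_theta=delta_theta
    )
    spline = cl.fit_centerline(sections, residual_tol=residual_tol)

    lo, hi = spline.domain
    grid = np.arange(lo, hi + 1e-9, 1.0)
    truth_local = frame.world_to_local(result.truth.centerline(grid))
    err = np.linalg.norm(spline.point(grid) - truth_local, axis=1)

    tc = np.arange(theta_step, theta_max + 1e-9, theta_step)
    tc = tc[(tc >= lo) & (tc <= hi)]
    tan_fit = spline.tangent(tc)
    tan_truth = frame.direction_to_local(result.truth.tangent(tc))
    cosang = np.clip(np.einsum("ij,ij->i", tan_fit, tan_truth), -1.0, 1.0)
    tangent_err = float(np.max(np.degrees(np.arccos(cosang))))

    plan = plan_targets(
        spline, result.mesh, frame=frame, theta_step=theta_step, theta_max=theta_max
    )
    targets = np.vstack([t.target for t in plan])
    residuals = result.truth.surface_distance(targets)

    return RecoveryReport(
        n_vertices=result.mesh.n_vertices,
        n_truncated=int(truncated.shape[0]),
        n_sections=len(sections),
        centerline_mean_error=float(np.mean(err)),
        centerline_max_error=float(np.max(err)),
        tangent_max_error_deg=tangent_err,
        target_surface_max_residual=float(np.max(residuals)),
        n_trajectories=len(plan),
        frame=frame,
        spline=spline,
        sections=sections,
        plan=plan,
        phantom=result,
    )
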