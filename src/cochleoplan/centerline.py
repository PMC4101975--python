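"""Scala tympani centerline extraction.

Working in the local cochlear frame, the labyrinth surface is reduced to the
basal scala tympani (ST) in three steps:

1. *Truncation* — keep vertices with strictly positive y and strictly
   negative z.  The x-y plane is the assumed basilar-membrane plane, so the
   ST (which lies inferior to the membrane in the basal half turn) sits at
   z < 0, and y > 0 restricts to the first half turn (0 < theta < 180 deg).
2. *Radial cross sections* — partition the surviving vertices into angular
   bins of width ``delta_theta`` (default 5 deg) centered at
   {0, 5, ..., 180} deg by nearest bin center; within each bin an iterative
   width filter trims points farther than the assumed ST width ``|R - I|``
   from the running centroid, rejecting nearby non-ST structures (vestibule,
   hook region, later turns).  The centroid (unweighted mean) of each
   surviving bin is one sample of the mid-scala course.
3. *Spline fit* — per-coordinate cubic smoothing splines of (x, y, z)
   against theta, with the smoothing factor chosen as the largest that keeps
   the maximum 3-D residual at the centroids below ``residual_tol``
   (default 0.05 mm; 0 gives exact interpolation).

Tangents of the fitted spline, oriented toward increasing theta (deeper
insertion), define the ideal insertion trajectories.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import LSQUnivariateSpline, UnivariateSpline

from .errors import SectionError, SplineError, TruncationError
from .frame import basal_angles

__all__ = [
    "CrossSection",
    "CenterlineSpline",
    "truncate_to_basal_st",
    "width_filter",
    "bin_cross_sections",
    "fit_centerline",
    "spline_point",
    "spline_tangent",
]


@dataclasses.dataclass(frozen=True)
class CrossSection:
    """One radial cross section of the basal ST (local frame).

    ``member_indices`` index into the point array passed to
    :func:`bin_cross_sections` (post width-filter survivors).
    """

    theta: float
    member_indices: np.ndarray
    centroid: np.ndarray
    n_removed_by_width: int
    #: fraction of the bin's angular width that can contain points; the two
    #: bins centered on the range boundaries are only half covered and their
    #: centroids carry an asymmetric-coverage bias
    coverage: float = 1.0


def truncate_to_basal_st(
    points_local: np.ndarray, return_indices: bool = False
):
    """Keep points with y > 0 and z < 0 (strict; boundary points excluded).

    The boundaries are excluded because z = 0 is the assumed membrane plane
    itself and y = 0 is the 0/180-degree reference plane.
    """
    p = np.asarray(points_local, dtype=float)
    mask = (p[:, 1] > 0.0) & (p[:, 2] < 0.0)
    if not np.any(mask):
        raise TruncationError(
            "no basal ST surface found (no vertices with y > 0 and z < 0); "
            "check the frame orientation / ear side"
        )
    idx = np.nonzero(mask)[0]
    if return_indices:
        return p[idx], idx
    return p[idx]


def _half_sample_center(points: np.ndarray, max_iter: int = 50) -> np.ndarray:
    """Robust cluster center: iterated mean of the nearest half of the points.

    Re-averaging only the half sample closest to the running center walks the
    center onto the dominant (densest) cluster, so a minority structure a few
    mm away cannot drag it off the scala tympani section.
    """
    center = points.mean(axis=0)
    n_half = (points.shape[0] + 1) // 2
    for _ in range(max_iter):
        dist = np.linalg.norm(points - center, axis=1)
        nearest = np.argpartition(dist, n_half - 1)[:n_half]
        new_center = points[nearest].mean(axis=0)
        if np.allclose(new_center, center, atol=1e-12):
            break
        center = new_center
    return center


def _width_filter_mask(points: np.ndarray, st_width: float) -> np.ndarray:
    """Iterative centroid trimming seeded at a robust cluster center.

    Points farther than ``st_width`` from the half-sample center are
    discarded, then the plain trim (discard beyond ``st_width`` of the mean
    of the kept set, recompute, repeat) runs to its fixed point.  The kept
    set shrinks monotonically, so termination is guaranteed; the mask may
    come back all-False only if every point is isolated beyond ``st_width``.
    """
    center = _half_sample_center(points)
    mask = np.linalg.norm(points - center, axis=1) <= st_width
    while np.any(mask):
        centroid = points[mask].mean(axis=0)
        keep = (np.linalg.norm(points - centroid, axis=1) <= st_width) & mask
        if np.array_equal(keep, mask):
            break
        mask = keep
    return mask


def width_filter(section_points: np.ndarray, st_width: float) -> np.ndarray:
    """Trim section points farther than ``st_width`` from the running centroid.

    Iterates (centroid -> discard -> recompute) to a fixed point; the kept
    set shrinks monotonically, so termination is guaranteed.  Raises
    :class:`SectionError` if every point is trimmed.
    """
    p = np.asarray(section_points, dtype=float).reshape(-1, 3)
    if p.shape[0] == 0:
        raise SectionError("width filter received an empty section")
    if st_width <= 0:
        raise SectionError(f"st_width must be positive, got {st_width}")
    mask = _width_filter_mask(p, st_width)
    if not np.any(mask):
        raise SectionError("section collapsed under width filter")
    return p[mask]


def bin_cross_sections(
    points_local: np.ndarray,
    st_width: float,
    delta_theta: float = 5.0,
    theta_range: Tuple[float, float] = (0.0, 180.0),
) -> List[CrossSection]:
    """Partition truncated ST points into radial sections and compute centroids.

    Bins are centered at ``theta_range[0], +delta_theta, ..., theta_range[1]``
    and each point goes to the nearest bin center by basal angle (a strict
    partition).  The width filter runs per bin; bins emptied by it (or never
    populated) are dropped.  Requires at least 4 surviving sections.
    """
    p = np.asarray(points_local, dtype=float)
    lo, hi = float(theta_range[0]), float(theta_range[1])
    if delta_theta <= 0:
        raise SectionError(f"delta_theta must be positive, got {delta_theta}")
    n_bins = int(round((hi - lo) / delta_theta))
    if abs(lo + n_bins * delta_theta - hi) > 1e-9:
        raise SectionError(
            f"delta_theta = {delta_theta} does not divide the range [{lo}, {hi}]"
        )
    theta = basal_angles(p)
    k = np.rint((theta - lo) / delta_theta).astype(int)
    in_range = (k >= 0) & (k <= n_bins)
    sections: List[CrossSection] = []
    for kk in range(n_bins + 1):
        idx = np.nonzero(in_range & (k == kk))[0]
        if idx.size == 0:
            continue
        mask = _width_filter_mask(p[idx], st_width)
        n_removed = int(idx.size - np.count_nonzero(mask))
        idx = idx[mask]
        if idx.size == 0:
            continue
        centroid = p[idx].mean(axis=0)
        sections.append(
            CrossSection(
                theta=lo + kk * delta_theta,
                member_indices=idx,
                centroid=centroid,
                n_removed_by_width=n_removed,
                coverage=0.5 if kk in (0, n_bins) else 1.0,
            )
        )
    if len(sections) < 4:
        raise SectionError(
            f"insufficient sections for spline: {len(sections)} survive, need >= 4"
        )
    return sections


@dataclasses.dataclass
class CenterlineSpline:
    """Smoothed cubic spline through section centroids, parameterized by theta.

    Evaluable (and once-differentiable) on ``domain`` only; no extrapolation.
    """

    theta_knots: np.ndarray
    domain: Tuple[float, float]
    residual_tol: float
    max_residual: float
    #: effective smoothing scale: spacing (deg) of the interior spline knots
    #: selected by the fit; 0 means exact interpolation
    smoothing: float
    _splines: tuple

    def _check_domain(self, theta) -> np.ndarray:
        t = np.asarray(theta, dtype=float)
        lo, hi = self.domain
        if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
            raise SplineError(
                f"theta outside spline domain [{lo}, {hi}] deg (no extrapolation)"
            )
        return np.clip(t, lo, hi)

    def point(self, theta) -> np.ndarray:
        """Spline point(s) at theta (deg); scalar -> (3,), array -> (n, 3)."""
        t = self._check_domain(theta)
        out = np.stack([s(t) for s in self._splines], axis=-1)
        return out

    def tangent(self, theta) -> np.ndarray:
        """Unit tangent(s) d(spline)/d(theta), oriented toward increasing theta."""
        t = self._check_domain(theta)
        d = np.stack([s.derivative()(t) for s in self._splines], axis=-1)
        norm = np.linalg.norm(d, axis=-1, keepdims=True)
        if np.any(norm < 1e-12):
            raise SplineError("degenerate (zero) tangent on the centerline spline")
        return d / norm


def _fit_at_segments(
    theta: np.ndarray,
    cents: np.ndarray,
    n_seg: int,
    weights: Optional[np.ndarray] = None,
    criterion_mask: Optional[np.ndarray] = None,
):
    """Least-squares cubic regression splines with n_seg uniform segments."""
    lo, hi = theta[0], theta[-1]
    interior = lo + (hi - lo) * np.arange(1, n_seg) / n_seg
    splines = tuple(
        LSQUnivariateSpline(theta, cents[:, i], interior, w=weights, k=3)
        for i in range(3)
    )
    pts = np.stack([sp(theta) for sp in splines], axis=-1)
    dist = np.linalg.norm(pts - cents, axis=1)
    if criterion_mask is not None:
        dist = dist[criterion_mask]
    return splines, float(np.max(dist))


def fit_centerline(
    sections: Sequence[CrossSection], residual_tol: float = 0.05
) -> CenterlineSpline:
    """Fit per-coordinate cubic smoothing splines to the section centroids.

    Smoothing is controlled by the spacing of the spline's interior knots
    (shared by the three coordinates): the fit walks a ladder of uniform
    spacings from one cubic segment over the whole domain down to twice the
    centroid spacing, and keeps the *coarsest* spacing — the largest amount
    of smoothing — for which the maximum 3-D distance between the spline
    and any (fully covered) centroid stays within ``residual_tol`` (mm).
    ``residual_tol = 0`` yields exact interpolation.

    Each centroid is parameterized by its *own* basal angle rather than the
    nominal bin center: a boundary bin is only half covered, so its centroid
    sits up to half a bin width away from the nominal center in azimuth, and
    parameterizing it there would bend the spline ends spuriously.  When the
    centroid angles are not strictly increasing (possible only for inputs
    that do not wind about the z-axis), the nominal section angles are used
    instead.
    """
    if len(sections) < 4:
        raise SplineError(f"need >= 4 sections to fit a cubic spline, got {len(sections)}")
    theta = np.asarray([s.theta for s in sections], dtype=float)
    if np.any(np.diff(theta) <= 0):
        raise SplineError("section angles must be strictly increasing")
    try:
        theta_c = basal_angles(np.vstack([s.centroid for s in sections]))
    except Exception:
        theta_c = theta
    if np.all(np.diff(theta_c) > 0):
        theta = theta_c
    if residual_tol < 0:
        raise SplineError(f"residual_tol must be >= 0, got {residual_tol}")
    cents = np.vstack([s.centroid for s in sections])
    coverage = np.asarray([getattr(s, "coverage", 1.0) for s in sections], dtype=float)
    # Half-covered boundary bins get half weight in the fit and are excluded
    # from the residual criterion: their centroids carry a systematic
    # asymmetric-coverage bias that no smooth curve can honor.
    weights = coverage
    full = coverage >= 1.0
    criterion_mask = full if np.count_nonzero(full) >= 4 else None

    def _interpolate():
        splines = tuple(
            UnivariateSpline(theta, cents[:, i], k=3, s=0.0) for i in range(3)
        )
        pts = np.stack([sp(theta) for sp in splines], axis=-1)
        return splines, float(np.max(np.linalg.norm(pts - cents, axis=1)))

    if residual_tol == 0.0:
        splines, resid = _interpolate()
        s_used = 0.0
    else:
        span = float(theta[-1] - theta[0])
        # knot spacing no finer than twice the centroid spacing, so every
        # knot interval keeps enough data for a stable least-squares fit
        n_max = max(1, int(np.floor(span / (2.0 * float(np.max(np.diff(theta)))))))
        chosen = None
        for n_seg in range(1, n_max + 1):
            cand, r = _fit_at_segments(theta, cents, n_seg, weights, criterion_mask)
            if r <= residual_tol:
                chosen = (cand, r, span / n_seg)
                break
        if chosen is None:
            # centroid scatter exceeds the tolerance at every admissible
            # knot spacing: only interpolation honors the residual bound
            warnings.warn(
                "no regression-spline knot spacing reaches residual_tol = "
                f"{residual_tol} mm; falling back to interpolation",
                stacklevel=2,
            )
            splines, resid = _interpolate()
            s_used = 0.0
        else:
            splines, resid, s_used = chosen
    return CenterlineSpline(
        theta_knots=theta,
        domain=(float(theta[0]), float(theta[-1])),
        residual_tol=float(residual_tol),
        max_residual=float(resid),
        smoothing=float(s_used),
        _splines=splines,
    )


def spline_point(spline: CenterlineSpline, theta) -> np.ndarray:
    """Evaluate the centerline at theta (deg, inside the spline domain)."""
    return spline.point(theta)


def spline_tangent(spline: CenterlineSpline, theta) -> np.ndarray:
    """Unit tangent of the centerline at theta, toward increasing theta."""
    return spline.tangent(theta)
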