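# Methods

## The anatomical model

The package plans cochleostomy targets and insertion trajectories for the
scala tympani (ST) using only structures visible in clinical CT: the bony
labyrinth surface and four point landmarks.  The local cochlear frame is
built from the landmarks R (round-window center at the bony overhang),
C (basal center of the modiolus, the origin), A (apical modiolar center)
and I (inner wall at the 0° reference):

* **x-axis** = normalize(R − C), exactly.  R anchors the 0° reference of
  every basal-turn angle, so it is taken exact.
* **z-axis** = the component of (A − C) orthogonal to x, normalized
  (Gram–Schmidt).  "x through R" and "z through A" cannot both hold for
  independently picked landmarks; the modiolar direction absorbs the
  non-orthogonality.
* **y-axis** = z × x (right-handed), then sign-resolved so the ST lies at
  positive y: kept for a right ear, flipped for a left ear (recorded as
  handedness −1).  With `side="auto"`, labyrinth vertices within 2 mm of R
  vote; y is flipped when fewer than half have positive y.

Two simplifying assumptions make the basal ST computable from the surface
alone: the basilar membrane lies in the local x-y plane (so the ST is the
region y > 0, z < 0 over the first half turn), and the ST width nowhere
exceeds |R − I|.  Both are anatomy-motivated approximations; the membrane
actually deviates from the plane by a couple tenths of a millimetre in the
region that matters, which is acceptable at drilling accuracy scales.

## Centerline extraction

Truncation keeps vertices with strictly positive y and strictly negative z
(the planes themselves belong to the membrane and to the 0°/180° reference,
so boundary points are excluded).  The surviving points are partitioned by
basal angle θ = atan2(y, x) into bins centered at 0°, 5°, …, 180°
(nearest-center assignment — a strict partition; Δθ = 5° default).

Within each bin a width filter removes points that cannot belong to the ST
section: points farther than |R − I| from the running centroid are
discarded and the centroid recomputed, iterated to a fixed point.  The
iteration is *seeded* at a robust half-sample center (the iterated mean of
the nearest half of the points), because the plain mean of a contaminated
bin can sit between the ST and a nearby structure in a way that either
stalls the trim with contaminants inside the radius or, for a dense
distractor, captures the filter entirely.  The half-sample seed locks onto
the dominant cluster first; the subsequent fixed-point trim then has the
spec'd semantics.  Termination is guaranteed (the kept set shrinks
monotonically).

Each surviving bin contributes its unweighted vertex mean (center of
gravity).  Bins at 0° and 180° are only half covered — points exist on one
side of the bin center only — so their centroids sit up to half a bin
width off-center in azimuth and carry an asymmetric-coverage bias; they
are marked `coverage = 0.5`.

**Centroid bias.** The centroid of the *surface* of a tube section is not
the tube center: truncating the arc above the membrane plane shifts the
mean of the remaining arc away from the removed part.  For tube radius
r = 0.6 mm with the section center 0.8 r below the plane, the analytic
arc-centroid offset is ≈ 0.14 mm.  This bias, not noise, dominates the
centerline recovery error; it is smooth in θ, so tangents (which is what
trajectories use) are essentially unaffected.

## Centerline spline and smoothing

Per-coordinate cubic splines of (x, y, z) against θ are fit to the
centroids.  Knot parameters are each centroid's *own* basal angle (for the
interior bins this equals the bin center to within centroid jitter; for
the half-covered boundary bins it is the honest parameter).  Smoothing
uses least-squares regression splines with uniform interior knots: the fit
walks segment counts from one (a single cubic) upward and keeps the
*coarsest* knot spacing whose maximum 3-D residual over fully covered
sections is within `residual_tol` (default 0.05 mm) — i.e. the largest
amount of smoothing the tolerance admits.  Boundary bins get half weight
and are excluded from the criterion; their systematic bias would otherwise
force near-interpolation globally.  `residual_tol = 0` gives exact
interpolation; if no admissible spacing exists (centroid scatter larger
than the tolerance, e.g. heavy vertex noise) the fit falls back to
interpolation with a warning, which is the only member of the family that
still honors the residual bound.  Knot spacing is floored at twice the
centroid spacing so every segment is data-supported.

Tangents are normalized derivatives with respect to θ, oriented toward
increasing θ (deeper insertion); no extrapolation outside the knot range.

## Trajectories and cochleostomy targets

The ideal trajectory at cochleostomy angle θ_C is the centerline tangent
there.  The target is found by casting a ray from the spline point
*against* the insertion direction (outward, toward the round-window region)
and taking the nearest ray/triangle intersection over all mesh triangles
(Möller–Trumbore, winding-agnostic, t > 10⁻⁹ mm to avoid self-hits;
degenerate triangles are counted and skipped).  The sweep covers
θ_C ∈ {2°, 4°, …, 20°}; θ_C = 0 is the round window itself, not a
cochleostomy, and is excluded.  For shells with inner and outer bone
layers the first hit is the endosteal surface — the drilling stop.

## Evaluation metrics

* **δ / ε** (degrees, signed): with u the ideal and v the planned insertion
  direction in the local frame, δ = asin(u_z) − asin(v_z); positive when
  the plan dips farther below the membrane plane than the ideal, negative
  δ flags membrane collision risk.  ε is the signed angle from the
  projected ideal tangent to the projected plan in the x-y plane, positive
  toward the outward radial direction (lateral wall), negative toward the
  modiolus.  The radial reference is orthonormalized against the projected
  tangent so that ε(u, u) = 0 identically — for a spiral (non-circular)
  centerline the raw radial direction is not orthogonal to the tangent.
* **Fiducial registration**: least-squares proper rigid transform (Kabsch,
  SVD with reflection guard) on paired screw centers; FRE is the RMS
  residual.  The physical workflow registers screw *surfaces*; point-based
  registration on screw centers is the standard desk equivalent.
* **Target error**: perpendicular distance from the planned target to the
  drilled trajectory axis (drilled tunnels are segmented as axes).
* **Membrane-plane error**: mean |z| of a membrane point set per 5° bin,
  plus the mean over an angular window (default 45–60°, the region used
  for trajectory computation).
* **Angular insertion depth**: basal angles of the contacts, unwrapped
  monotonically from the most basal contact (+360° per wrap); the depth is
  the unwrapped angle of the most apical contact.  Contacts must be given
  basal→apical; no re-ordering is attempted.

## The phantom

The phantom is a spiral tube emulating the ST: centerline
c(θ) = (ρ cos θ, ρ sin θ, z(θ)) with ρ(θ) = a·e^(−bθ) (a = 3 mm;
b chosen so ρ(360°) = 0.6 a), z = −0.8 r for θ ≤ 180° (planar basal half
turn, tube center 0.8 r below the membrane plane) rising with 1.8 mm per
turn thereafter; tube radius r = 0.6 mm tapering linearly to half at the
apex (the ST roughly halves toward the apex).  The default mesh is the
capped basal half-turn tube — watertight at zero noise, with unique
vertices (no triangle soup).  Landmarks by construction: C at the origin,
A on the z-axis above the apex, R at membrane level directly above the
centerline start (the round window sits at basilar-membrane level, the
lumen center below it), I one tube diameter inward, so |R − I| = 2r.

Two constructional choices matter for what the phantom can measure:

* Rings are drawn in *radial* planes (containing the z-axis) — the same
  planes the cross-section binning samples — at half-step angular offsets
  (1°, 3°, …, 179° at the default 2° resolution).  Radial rings make every
  ring share exactly one basal angle, so bins are unions of whole rings
  and the binning cannot alias against the mesh structure; the half-step
  offset keeps vertices off the y = 0 truncation planes, where
  plane-sitting points would flip membership under rigid transforms of
  the whole phantom.  Rings differ from tangent-perpendicular sections by
  under 1% (cosine of the 4.7° spiral pitch angle).
* The membrane ground truth is the analytic locus where the tube wall
  crosses z = 0 — exactly in-plane, so the phantom satisfies the membrane
  assumption with zero error and any measured membrane error is the
  pipeline's.

Distractors (off by default) add the structures the filters must reject:
a vestibule-like blob entirely above the membrane plane (truncation's
job), a small coplanar blob 5 mm outside the basal turn (the width
filter's job), and the spiral continuation through the upper turns, whose
start dips a few hundredths of a millimetre below the membrane plane near
θ = 360° — the hardest case, since those points sit just beyond |R − I|
from the true section.  Gaussian vertex noise (`noise_sd`) is applied
after landmark/truth construction; a fixed seed gives byte-identical
phantoms.

**What the phantom does not emulate**: the hook region's out-of-plane
membrane course near the round window, anatomical cross-section shapes
(real ST sections are not circular), segmentation topology errors (holes,
handles), and partial-volume noise correlated along the surface rather
than i.i.d. per vertex.  Passing recovery tests therefore demonstrates the
pipeline's geometric correctness and its robustness to the modeled
perturbations, not clinical-grade accuracy on real segmentations.

## Expected magnitudes on the default phantom

* Centerline mean error ≈ 0.13 mm (≤ 0.15 mm bound): the truncated-arc
  centroid bias at r = 0.6 mm, as derived above.
* Tangent error ≤ 5° over θ_C ∈ [2°, 20°] (measured ≈ 3.4°): boundary-bin
  handling plus regression-spline end behavior.
* With 0.05 mm i.i.d. vertex noise the centroid noise averages down by
  1/√(points per bin) ≈ 1/7, so the centerline mean error stays ≈ 0.12 mm
  (≤ 0.25 mm bound over 20 seeds).
* Distractors displace the fitted centerline by < 0.05 mm; mirroring the
  phantom (left ear) with the side flag flipped reproduces the plan
  exactly (sign-exact arithmetic).
* Noisy-fiducial FRE with 6 screws and σ = 0.1 mm isotropic noise has
  expectation σ·√3·√(1 − 6/18) ≈ 0.14 mm (6 of the 18 coordinate degrees
  of freedom are absorbed by the rigid fit).

## Numerical choices

* Strict inequalities for truncation; tolerance 10⁻⁹ for frame
  orthogonality checks; ray t_eps = 10⁻⁹ mm; triangles with area
  < 10⁻¹² mm² treated as degenerate.
* Nearest-bin assignment by `rint(θ/Δθ)`; ties cannot arise for the
  phantom's half-step vertex angles.
* Angle unit is degrees throughout the public interface; radians only
  inside trigonometric kernels.
* Plan and landmark JSON round-trip floats exactly (double precision);
  STL I/O is float32, so mesh round trips agree to ~2·10⁻⁷ relative.
* The |R − I| width bound is interpreted as a *radius* about the section
  centroid (the most permissive reading); the robust seeding documented
  above compensates for the permissiveness.

## Known limitations

* The cross-section extraction assumes a star-shaped basal turn about the
  modiolar axis; basal-turn ossification or malformations violate this.
* The centroid bias (~0.14 mm toward the open side of the truncated
  section) is inherent to the center-of-gravity construction; a model-based
  section fit (circle/ellipse) would remove it but is out of scope.
* The spline's boundary segments are least constrained; trajectories at
  θ_C = 2° sit closest to the domain edge and carry the largest tangent
  uncertainty.
* Mesh units are taken as millimetres verbatim; no unit detection.
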