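# cochleoplan

Landmark-based planning of scala tympani (ST) cochleostomy targets and
electrode insertion trajectories from segmented inner-ear surface meshes.

## The problem

Minimally invasive cochlear implantation drills a narrow tunnel from the
mastoid surface to the cochlea and opens the ST through a cochleostomy.
Atraumatic electrode placement needs two things clinical CT cannot show
directly: the position of the basilar membrane and the mid-scala course of
the ST.  This package implements a semiautomatic workaround: four easily
identified landmarks — the round-window center **R**, the basal modiolar
center **C**, the apical modiolar center **A**, and the inner wall at the
0° reference **I** — define a local cochlear coordinate system (origin at
C, x-axis through R, z-axis along the modiolus toward A) in which the
basilar membrane is approximated by the x-y plane and the ST width is
bounded by |R − I|.

From a triangulated labyrinth surface the pipeline then

1. truncates the vertex set to the basal ST (y > 0, z < 0 in the local frame),
2. partitions it into radial cross sections every Δθ = 5° over the first
   basal half turn (0–180°), trimming non-ST structures with the
   |R − I| width bound and taking each section's center of gravity,
3. fits a smoothed cubic spline c(θ) through the centroids — the mid-scala
   centerline — and
4. defines the ideal insertion trajectory at a cochleostomy angle θ_C as the
   tangent dc/dθ, locating the cochleostomy target where that line,
   followed outward, first exits the surface (Möller–Trumbore ray/triangle
   intersection), swept in 2° steps up to θ_C = 20°.

Evaluation metrics mirror image-guided-surgery practice: signed alignment
angles δ (out-of-plane; negative = basilar-membrane collision risk) and ε
(in-plane; negative = modiolus collision risk) between a planned and the
ideal trajectory, point-based rigid (Kabsch) fiducial registration with its
FRE, perpendicular target error to a drilled axis, the membrane-plane
approximation error (mean |z| per angular bin), and the unwrapped angular
insertion depth of an electrode array.

A synthetic phantom — a logarithmic-spiral tube with analytic centerline,
landmarks placed by construction, an exact in-plane membrane locus and
optional distractor structures — makes every stage testable without
clinical data.  Intended users: researchers in computer-assisted ENT
surgery who want a reference implementation of landmark-based ST planning
with a fully characterized synthetic test bed.

## Worked example

```bash
python examples/plan_cochleostomy.py
```

prints (abridged):

```
phantom: 2162 vertices, 1754 on the basal scala tympani after truncation
cross sections: 37 (every 5 deg over the basal half turn)
centerline spline: domain 1.0 to 179.0 deg, max residual 0.027 mm

theta_C   target (world mm)           exit distance
     2   ( 2.975,  0.052, -0.633)      0.034 mm
     4   ( 2.979,  0.052, -0.633)      0.145 mm
    ...
    20   ( 3.178,  0.055, -0.628)      1.044 mm

  centerline mean error : 0.127 mm
  tangent error (max)   : 3.36 deg over theta_C 2-20 deg
```

The 37 cross sections cover the basal half turn; the ten targets are the
cochleostomy candidates at θ_C = 2°…20°, all inferior to the round window,
with exit distances growing as the cochleostomy moves deeper along the
basal turn.  The 0.127 mm centerline error against the phantom's analytic
truth is almost entirely the systematic centroid bias of averaging surface
points over a truncated tube section — the intrinsic accuracy floor of the
center-of-gravity construction at this tube radius (0.6 mm).

Two further examples cover trajectory evaluation
(`examples/evaluate_alignment.py`: δ/ε angles, noisy fiducial registration,
drilled-axis target error) and the membrane / insertion-depth metrics
(`examples/membrane_and_depth.py`).

There is also a small CLI:

```bash
cochleoplan phantom --out-dir demo --seed 1
cochleoplan plan demo/phantom.stl demo/landmarks.json --out demo/plan.json
cochleoplan evaluate demo/plan.json --drilled-axis axis.json --out metrics.csv
```

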