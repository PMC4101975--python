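"""Plan cochleostomy targets on a synthetic cochlea.

Generates the default spiral-tube phantom (a stand-in for a segmented
scala tympani with its four anatomical landmarks), runs the full planning
pipeline and prints the cochleostomy sweep: for each basal-turn angle
theta_C the tangent insertion trajectory and the point where it exits the
labyrinth surface — the drill target on the promontory / round-window
region.
"""
import numpy as np

from cochleoplan import PhantomSpec, end_to_end_recovery

report = end_to_end_recovery(PhantomSpec())

print(f"phantom: {report.n_vertices} vertices, "
      f"{report.n_truncated} on the basal scala tympani after truncation")
print(f"cross sections: {report.n_sections} (every 5 deg over the basal half turn)")
print(f"centerline spline: domain {report.spline.domain[0]:.1f} to "
      f"{report.spline.domain[1]:.1f} deg, max residual {report.spline.max_residual:.3f} mm")
print()
print("theta_C   target (world mm)           exit distance")
for traj in report.plan:
    x, y, z = traj.target
    print(f"  {traj.theta_c:4.0f}   ({x:6.3f}, {y:6.3f}, {z:6.3f})      {traj.exit_distance:.3f} mm")
print()
print("Against the analytic ground truth of the phantom:")
print(f"  centerline mean error : {report.centerline_mean_error:.3f} mm "
      "(dominated by the centroid-of-surface bias of cross-section averaging)")
print(f"  tangent error (max)   : {report.tangent_max_error_deg:.2f} deg over theta_C 2-20 deg")
print(f"  targets off surface by at most {report.target_surface_max_residual:.4f} mm")
print()
print("Exit distances grow with theta_C: deeper cochleostomies sit farther")
print("from the round window along the basal turn.")
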