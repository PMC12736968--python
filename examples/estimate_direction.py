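"""Estimate the movement-artifact direction and magnitude from one frame.

The estimator never sees the ground truth: it crops the object, scans four
directional scanline families for self-similar replicas, and reads the
direction from the 3-D octagon vote.  theta is the estimated axis in degrees
(its complement is equally valid — blur is bidirectional), q the weighted
artifact magnitude in pixels, and the per-direction lines show how many
scanlines detected a displacement in each family.
"""

from made import MotionParameters, PSFSpec, estimate, orientation_error, render_object_trail

truth_phi = 30.0
frame = render_object_trail(MotionParameters(v=0.24, phi=truth_phi), PSFSpec())

est = estimate(frame.intensities)

print(f"true orientation  : {truth_phi:.1f} deg")
print(f"estimated theta   : {est.theta:.1f} deg (complement {est.theta_complement:.1f})")
print(f"orientation error : {orientation_error(est.theta, truth_phi):.1f} deg")
print(f"weighted magnitude: {est.q:.2f} px  (boundary segment {est.segment})")
for name, d in est.stats.per_direction().items():
    print(f"  {name:12s} mean {d['mean']:5.2f} px  detections {d['n_valid']:3d}/{d['n_lines']}")
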