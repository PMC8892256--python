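"""Cable lengths for planar trajectories and the bimanual handlebar.

Builds the default geometry (1.0 m frame, 0.5 m handlebar), discretizes a
20 cm circle into a square (N = 4), prints the cable-length pair at each
vertex, then shows the bimanual forward/inverse models round-tripping a
rotation angle.
"""

import math

from bicar.kinematics import (
    HandlebarState,
    PlanarPoint,
    RobotGeometry,
    TrajectorySpec,
    bimanual_cable_lengths,
    handlebar_orientation,
    planar_cable_lengths,
    trajectory_points,
)

geom = RobotGeometry(frame_width_Wb=1.0, handlebar_width_Wg=0.5)

spec = TrajectorySpec(center=PlanarPoint(0.0, 0.6), diameter_a=0.2, n_points_N=4)
print("Square trajectory (vertices of a 20 cm circle), cable lengths in m:")
for i, p in enumerate(trajectory_points(spec, geom), start=1):
    L = planar_cable_lengths(p, geom)
    print(f"  vertex {i}: P=({p.xp:+.3f}, {p.yp:.3f})  L1={L.L1:.4f}  L2={L.L2:.4f}")
# Equal lengths on the vertical midline; shorter L1 when P moves left.

theta = math.radians(15.0)
state = HandlebarState(height_h=0.7, angle_theta=theta)
L = bimanual_cable_lengths(state, geom)
back = handlebar_orientation(L, h=0.7, geom=geom)
print(f"\nHandlebar at h=0.70 m rotated {math.degrees(theta):.1f} deg CCW:")
print(f"  L1={L.L1:.6f} m, L2={L.L2:.6f} m (left cable longer: left tip drops)")
print(f"  inverse model recovers theta = {math.degrees(back):.6f} deg")
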