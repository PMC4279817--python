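"""Discretize the gait curve into a robot trajectory at a 0.5-deg increment.

Points sit where the flexion curve crosses half-degree angle levels; adjacent
equal-angle points at extrema merge to their midpoint; the commanded velocity
is the circular angle differential normalized to a 10 deg/s peak; the axial
force command is interpolated at each point's gait percent.
"""

import numpy as np

from robogait import GaitTemplateParams, build_trajectory, correct_cycle_junction, generate_gait_template

curve = correct_cycle_junction(generate_gait_template(GaitTemplateParams()))
traj = build_trajectory(curve, increment=0.5, v_max=10.0)

print(f"trajectory points: {traj.n}")
print(f"peak commanded velocity: {traj.velocity.max():.3f} deg/s (scaled target)")
print(f"slowest commanded velocity: {traj.velocity.min():.3f} deg/s (stance)")
print(f"axial force command range: {traj.axial_force.min():.2f} .. "
      f"{traj.axial_force.max():.2f} BW")
dtheta = np.abs(np.diff(traj.angle))
print(f"every step moves the joint: min |dtheta| = {dtheta.min():.2f} deg")
# The angle, velocity and force vectors share one length: together one row
# per robot waypoint of the simulated gait cycle.
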