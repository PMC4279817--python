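"""Optimal flexion increment and the 10 deg/s velocity cap.

Fine increments give smoother force profiles but the per-waypoint controller
latency throttles speed; the optimal increment is the smallest one that still
reaches the desired peak velocity.  Profiles commanded above the safety cap
execute at the cap, delaying the swing phase.
"""

import numpy as np

from robogait import (
    GaitTemplateParams,
    JointModelParams,
    RobotParams,
    build_loaded_path,
    build_trajectory,
    correct_cycle_junction,
    find_optimal_increment,
    generate_gait_template,
    generate_passive_path,
    max_achieved_velocity,
    simulate_execution,
)

curve = correct_cycle_junction(generate_gait_template(GaitTemplateParams()))
robot = RobotParams(n_cycles=1, n_precondition=0)
quiet = JointModelParams(noise_sd_axial=0, noise_sd_pa=0, noise_sd_ml=0,
                         cycle_jitter_sd=0)

candidates = (0.1, 0.2, 0.3, 0.4, 0.5, 0.75, 1.0)
best = find_optimal_increment(curve, candidates, v_target=10.0, robot=robot)
print(f"optimal increment: {best:g} deg "
      "(smallest increment still reaching 10 deg/s)")

for v_max in (10.0, 15.0, 20.0):
    traj = build_trajectory(curve, best, v_max)
    k = np.rint((traj.angle - traj.angle[0]) / best).astype(int)
    path = generate_passive_path(
        np.zeros(3), np.array([1.0, 0.0, 0.0]),
        start_angle=float(traj.angle[0] + k.min() * best),
        increment=best, span=float((k.max() - k.min()) * best),
    )
    loaded = build_loaded_path(traj, path, body_weight=300.0)
    trace = simulate_execution(loaded, path, robot, quiet)
    print(f"v_max {v_max:4.0f} deg/s -> achieved {max_achieved_velocity(trace):5.2f} "
          f"deg/s, cycle period {trace.cycle_period:5.2f} s")
# Commanding 15 or 20 deg/s still executes at the 10 deg/s cap; the period
# shrinks anyway because the slow stance portion scales with the command.
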