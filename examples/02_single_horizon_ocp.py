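"""Solve one finite-horizon optimal control problem by direct collocation.

A 0.3 s horizon from the natural posture toward a target 20 cm to the left,
minimizing tracking error (p = 20) plus squared excitation (q = 1).  Prints
the objective, solver diagnostics and how far the hand gets within the
horizon.
"""

import numpy as np

from reachmpc import (MeshSpec, OcpProblem, REFERENCE_POSTURE, SystemState,
                      default_model, forward_kinematics, solve_ocp)

arm, muscles = default_model()
x0 = SystemState(*REFERENCE_POSTURE)
zeta0 = forward_kinematics(x0.joint_angles, arm)
target = zeta0 + np.array([-0.20, 0.0])

spec = OcpProblem(t0=0.0, horizon=0.3, x0=x0.as_vector(),
                  tracking_weight=20.0, effort_weight=1.0, target=target,
                  mesh=MeshSpec(8, 3))
sol = solve_ocp(spec, arm, muscles)

hand_end = forward_kinematics(sol.states[-1, 0:2], arm)
print(f"solver: {sol.message} after {sol.n_iter} iterations")
print(f"objective J = {sol.objective:.5f} "
      f"(integral of 20*err^2 + sum u^2 over 0.3 s)")
print(f"max dynamics defect: {sol.defect_max:.2e}")
print(f"hand after the horizon: ({hand_end[0]:.4f}, {hand_end[1]:.4f}) m, "
      f"{np.linalg.norm(hand_end - target)*100:.2f} cm from the target")
print(f"peak excitation: {sol.controls.max():.3f} "
      f"(muscle {int(np.unravel_index(sol.controls.argmax(), sol.controls.shape)[1]) + 1})")
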