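"""Load the default planar arm, inspect its kinematics and muscle apparatus.

Prints the initial hand position, each muscle's moment arms at the natural
posture and the isometric force of the shoulder flexor at full drive.
"""

import numpy as np

from reachmpc import (REFERENCE_POSTURE, default_model, forward_kinematics,
                      muscle_force, muscle_geometry)

arm, muscles = default_model()
q0 = np.array(REFERENCE_POSTURE)

zeta0 = forward_kinematics(q0, arm)
print(f"hand at the natural posture (44/58 deg): "
      f"({zeta0[0]:.4f}, {zeta0[1]:.4f}) m from the shoulder")

lengths, R = muscle_geometry(q0, arm, muscles)
print("\nmuscle          path(cm)  r_shoulder(cm)  r_elbow(cm)")
for i, name in enumerate(muscles.names):
    print(f"{name:22s} {lengths[i]*100:6.1f} {R[0, i]*100:10.2f} "
          f"{R[1, i]*100:12.2f}")

F = muscle_force(1.0, 0, q0, np.zeros(2), arm, muscles)
print(f"\nshoulder flexor at full activation, optimal length, isometric: "
      f"{F:.1f} N (= F0max cos(pennation))")
# Positive moment arms flex (counter-clockwise); the three flexors pull the
# hand leftward, their antagonists rightward.
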