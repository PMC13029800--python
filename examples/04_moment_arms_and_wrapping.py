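"""Muscle moment arms via tendon excursion, with cylinder wrapping.

The moment arm is r(theta) = -dL/dtheta.  The rectus femoris path wraps the
knee cylinder in flexion, so its knee moment arm stays near the cylinder
radius (25 mm) through deep flexion instead of collapsing.
"""

import numpy as np

from mskwarp.muscle_mech import joint_grid, moment_arm, path_length
from mskwarp.synthetic import make_fixture_model

model = make_fixture_model()
knee = model.joint("knee_r")
grid = joint_grid(knee, 13)

print("rectus_femoris knee moment arm (m) over knee angle (deg):")
wf = moment_arm(model, "rectus_femoris", "knee_r", grid)
for angle, r in zip(np.degrees(wf.angles), wf.values):
    print(f"  {angle:7.1f}  {r:+.4f}")

L0 = path_length(model, "rectus_femoris", {})
L_flexed = path_length(model, "rectus_femoris", {"knee_r": np.deg2rad(-90)})
print(f"path length neutral: {L0:.4f} m, at 90 deg knee flexion: {L_flexed:.4f} m")
print(f"knee wrap cylinder radius: {model.wrap('knee_cyl_r').radius} m")
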