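"""Bone-geometry measures: segment lengths, pelvis dimensions, bone angles.

The femur/tibia lengths come from adjacent joint centers; the six pelvis
dimensions and the three bone angles (femoral torsion, neck-shaft, tibial
torsion) are computed from named landmarks.  The template is built with
12 deg anteversion, 125 deg neck-shaft and 15 deg external tibial torsion,
which the measures read back exactly.
"""

from mskwarp import build_template, add_joint_center_doubles
from mskwarp.anthropometry import bone_angles, pelvis_dimensions, segment_lengths
from mskwarp.synthetic import make_fixture_model

template = add_joint_center_doubles(build_template())
model = make_fixture_model(template)

lengths = segment_lengths(model, "r")
print("segment lengths (m):",
      {k: round(v, 4) for k, v in lengths.items()})

print("pelvis dimensions (mm):")
for name, value in pelvis_dimensions(template.landmarks).items():
    print(f"  {name:16s} {value:7.1f}")

print("bone angles (deg), right limb:")
for name, value in bone_angles(template.landmarks, "r").items():
    print(f"  {name:18s} {value:7.2f}")
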