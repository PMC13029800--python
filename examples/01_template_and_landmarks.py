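"""Build the homologous-landmark template and export it for 3D Slicer.

The template carries 106 named bone landmarks on pelvis, femora, patellae
and tibiae/fibulae (21 primary + 85 secondary), plus 4 joint-center doubles
added for parent/child frame bookkeeping.  The exported .fcsv can be loaded
in 3D Slicer to guide manual landmarking on a participant's MRI.
"""

from collections import Counter

from mskwarp import add_joint_center_doubles, build_template
from mskwarp.slicer_io import isb_to_ras, write_markups

template = build_template()
tiers = Counter(template.tier_of.values())
print(f"bone landmarks: {len(template.landmarks)} "
      f"({tiers['primary']} primary + {tiers['secondary']} secondary)")

doubled = add_joint_center_doubles(template)
print(f"with joint-center doubles: {len(doubled.landmarks)}")

segments = Counter(doubled.segment_of.values())
print("per segment:", dict(segments))

write_markups(isb_to_ras(doubled.landmarks), "template.fcsv")
print("wrote template.fcsv (RAS mm, loadable in 3D Slicer)")
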