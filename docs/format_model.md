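# Model JSON format (schema 1)

A model file is a single UTF-8 JSON object.  Unknown top-level fields are
preserved on round-trip (loaded with a warning, written back unchanged).
All positions are meters; the `coordinates` field says whether they are in
the global ISB frame (`"global"`) or per-segment local frames (`"local"`).

```json
{
 "schema": 1,
 "segments": ["pelvis", "femur_r", "..."],
 "joints": [
  {"name": "hip_r", "parent_segment": "pelvis", "child_segment": "femur_r",
   "center_global": [x, y, z], "axis": [0, 0, 1],
   "range": [min_rad, max_rad],
   "center_in_parent": [x, y, z] | null,
   "center_in_child":  [x, y, z] | null}
 ],
 "muscles": [
  {"name": "rectus_femoris",
   "points": [
    {"label": "origin", "segment": "pelvis", "position": [x, y, z],
     "role": "origin"},
    {"label": "P1", "segment": "femur_r", "position": [x, y, z], "role": "via"},
    {"label": "insertion", "segment": "patella_r", "position": [x, y, z],
     "role": "insertion"}
   ],
   "wraps": [["knee_cyl_r", 1]],
   "search_radius_of": {"P1": 0.005}}
 ],
 "wrap_surfaces": [
  {"name": "knee_cyl_r", "segment": "femur_r",
   "axis_point": [x, y, z], "axis_dir": [0, 0, 1],
   "radius": 0.025, "length": 0.10, "active_quadrant": "+x"}
 ],
 "skin_markers": {"names": ["RASI", "..."], "coords": [[x, y, z], "..."],
                  "frame": "ISB_global", "units": "m"},
 "strength": {"rectus_femoris": {"max_isometric_force": 1500.0,
                                 "optimal_fiber_length": 0.075}},
 "landmarks": {"names": ["..."], "coords": ["..."],
               "frame": "ISB_global", "units": "m"},
 "welds": [["patella_r", "tibia_r"]],
 "coordinates": "global",
 "metadata": {}
}
```

Notes

- `joints[].range` is in radians; `axis` must be unit length.
- `muscles[].wraps` entries are `[cylinder_name, i]`: the cylinder deflects
  the path segment between points `i` and `i+1`.
- `muscles[].search_radius_of` bounds via-point motion during optimization
  (meters); points not listed are immobile.
- `wrap_surfaces[].active_quadrant` (`"+x"`, `"-x"`, `"+y"`, `"-y"`, in the
  cylinder's local cross-sectional plane) selects the wrap side.
- `welds` are rigid child→parent attachments without a joint.
- When `coordinates` is `"local"`, `metadata.frames` holds each segment's
  `origin` and row-major rotation `R` (global→local), written by
  `mskwarp.frames.localize`.
- Validation (`mskwarp validate model.json` or
  `mskwarp.core.validate_model`) checks referential integrity and all
  numeric invariants.
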