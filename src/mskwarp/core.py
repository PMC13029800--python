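"""Domain types and the homologous-landmark template.

The toolkit personalizes a simplified bilateral lower-limb model (pelvis,
femora, patellae, tibiae/fibulae, feet) from named bone landmarks.  The
currency of every stage is the :class:`LandmarkSet`: an ordered, named set of
3D points with an explicit coordinate-frame tag and explicit units.  The
template ships 106 bone landmarks, split into a *primary* tier of 21 points
that an operator can place directly on MRI and a *secondary* tier of 85
points that are projected by thin-plate spline, plus 4 joint-center doubles
used to express hip and knee centers in both the parent and child segment
frames.

All canonical model coordinates are ISB-style global: x anterior, y superior,
z right; meters.  LandmarkSets may carry mm (e.g. straight from Slicer) and
are converted explicitly, never implicitly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

SCHEMA_VERSION = 1

SEGMENTS = (
    "pelvis",
    "femur_r", "femur_l",
    "patella_r", "patella_l",
    "tibia_r", "tibia_l",
    "foot_r", "foot_l",
)

TIERS = ("primary", "secondary", "joint_double")


class ModelFormatError(ValueError):
    """Raised when a model or markups file cannot be parsed."""


# ---------------------------------------------------------------------------
# LandmarkSet
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Named, ordered 3D points with frame and unit tags.

    Parameters
    ----------
    names:
        Unique landmark identifiers, order significant.
    coords:
        ``(N, 3)`` float array of positions.
    frame:
        ``"RAS"``, ``"ISB_global"`` or ``"ISB_segment:<segname>"``.
    units:
        ``"mm"`` or ``"m"``.
    """

    names: list[str]
    coords: np.ndarray
    frame: str
    units: str

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.names), 3)
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate landmark names: {dupes}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")
        if self.units not in ("mm", "m"):
            raise ValueError(f"units must be 'mm' or 'm', got {self.units!r}")
        if not self.frame:
            raise ValueError("frame tag must be set")

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def _index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.names)}

    def get(self, name: str) -> np.ndarray:
        try:
            return self.coords[self._index[name]].copy()
        except KeyError:
            raise KeyError(f"landmark {name!r} not in set") from None

    def subset(self, names: Sequence[str]) -> "LandmarkSet":
        idx = self._index
        missing = [n for n in names if n not in idx]
        if missing:
            raise KeyError(f"landmarks not in set: {missing}")
        rows = [idx[n] for n in names]
        return LandmarkSet(list(names), self.coords[rows].copy(), self.frame, self.units)

    def with_coords(self, coords: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(list(self.names), np.asarray(coords, float), self.frame, self.units)

    def to_m(self) -> "LandmarkSet":
        if self.units == "m":
            return self.copy()
        return LandmarkSet(list(self.names), self.coords / 1000.0, self.frame, "m")

    def to_mm(self) -> "LandmarkSet":
        if self.units == "mm":
            return self.copy()
        return LandmarkSet(list(self.names), self.coords * 1000.0, self.frame, "mm")

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(list(self.names), self.coords.copy(), self.frame, self.units)

    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "coords": self.coords.tolist(),
            "frame": self.frame,
            "units": self.units,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LandmarkSet":
        return cls(list(d["names"]), np.asarray(d["coords"], float), d["frame"], d["units"])


# ---------------------------------------------------------------------------
# Model geometry types
# ---------------------------------------------------------------------------

@dataclass
class JointDef:
    """A hinge joint between a parent and a child segment.

    Centers are stored three ways: in the neutral-pose global frame
    (``center_global``, used by kinematics) and re-expressed in the parent and
    child segment frames (filled by :func:`mskwarp.frames.localize`).
    """

    name: str
    parent_segment: str
    child_segment: str
    center_global: np.ndarray
    axis: np.ndarray
    range: tuple[float, float]
    center_in_parent: np.ndarray | None = None
    center_in_child: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.center_global = np.asarray(self.center_global, float).reshape(3)
        self.axis = np.asarray(self.axis, float).reshape(3)
        if self.center_in_parent is not None:
            self.center_in_parent = np.asarray(self.center_in_parent, float).reshape(3)
        if self.center_in_child is not None:
            self.center_in_child = np.asarray(self.center_in_child, float).reshape(3)
        self.range = (float(self.range[0]), float(self.range[1]))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "parent_segment": self.parent_segment,
            "child_segment": self.child_segment,
            "center_global": self.center_global.tolist(),
            "axis": self.axis.tolist(),
            "range": list(self.range),
            "center_in_parent": None if self.center_in_parent is None else self.center_in_parent.tolist(),
            "center_in_child": None if self.center_in_child is None else self.center_in_child.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "JointDef":
        return cls(
            d["name"], d["parent_segment"], d["child_segment"],
            np.asarray(d["center_global"], float), np.asarray(d["axis"], float),
            tuple(d["range"]),
            None if d.get("center_in_parent") is None else np.asarray(d["center_in_parent"], float),
            None if d.get("center_in_child") is None else np.asarray(d["center_in_child"], float),
        )


@dataclass
class WrapCylinder:
    """Analytic cylindrical obstacle deflecting a muscle path.

    ``active_quadrant`` names the direction (in the cylinder's local x-y
    plane, e.g. ``"+x"``) toward which the wrapped path is pushed; it picks
    one of the two tangent-arc-tangent solutions.
    """

    name: str
    segment: str
    axis_point: np.ndarray
    axis_dir: np.ndarray
    radius: float
    length: float
    active_quadrant: str = "+x"

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, float).reshape(3)
        self.axis_dir = np.asarray(self.axis_dir, float).reshape(3)
        self.radius = float(self.radius)
        self.length = float(self.length)

    def to_dict(self) -> dict:
        return {
            "name": self.name, "segment": self.segment,
            "axis_point": self.axis_point.tolist(), "axis_dir": self.axis_dir.tolist(),
            "radius": self.radius, "length": self.length,
            "active_quadrant": self.active_quadrant,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "WrapCylinder":
        return cls(d["name"], d["segment"], np.asarray(d["axis_point"], float),
                   np.asarray(d["axis_dir"], float), d["radius"], d["length"],
                   d.get("active_quadrant", "+x"))


@dataclass
class MusclePathPoint:
    label: str
    segment: str
    position: np.ndarray          # meters, frame given by model.coordinates
    role: str                     # origin | via | insertion

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float).reshape(3)
        if self.role not in ("origin", "via", "insertion"):
            raise ValueError(f"bad role {self.role!r}")

    def to_dict(self) -> dict:
        return {"label": self.label, "segment": self.segment,
                "position": self.position.tolist(), "role": self.role}

    @classmethod
    def from_dict(cls, d: Mapping) -> "MusclePathPoint":
        return cls(d["label"], d["segment"], np.asarray(d["position"], float), d["role"])


@dataclass
class MusclePathDef:
    """Polyline musculotendon path with optional wrap-cylinder assignments.

    ``wraps`` maps a wrap-cylinder name to the index ``i`` of the path point
    starting the segment (between points ``i`` and ``i+1``) that the cylinder
    deflects.  ``search_radius_of`` bounds via-point motion during
    optimization (meters).
    """

    name: str
    points: list[MusclePathPoint]
    wraps: list[tuple[str, int]] = field(default_factory=list)
    search_radius_of: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError(f"muscle {self.name}: needs >= 2 path points")
        if self.points[0].role != "origin" or self.points[-1].role != "insertion":
            raise ValueError(f"muscle {self.name}: first point must be origin, last insertion")

    def point(self, label: str) -> MusclePathPoint:
        for p in self.points:
            if p.label == label:
                return p
        raise KeyError(f"muscle {self.name}: no path point {label!r}")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "points": [p.to_dict() for p in self.points],
            "wraps": [[w, int(i)] for w, i in self.wraps],
            "search_radius_of": dict(self.search_radius_of),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MusclePathDef":
        return cls(d["name"], [MusclePathPoint.from_dict(p) for p in d["points"]],
                   [(w, int(i)) for w, i in d.get("wraps", [])],
                   dict(d.get("search_radius_of", {})))


@dataclass
class MuscleStrength:
    max_isometric_force: float   # N
    optimal_fiber_length: float  # m

    def to_dict(self) -> dict:
        return {"max_isometric_force": self.max_isometric_force,
                "optimal_fiber_length": self.optimal_fiber_length}

    @classmethod
    def from_dict(cls, d: Mapping) -> "MuscleStrength":
        return cls(float(d["max_isometric_force"]), float(d["optimal_fiber_length"]))


@dataclass
class ModelGeometry:
    """Segments, joints, muscle paths, wrap surfaces, skin markers, strength.

    ``coordinates`` records whether point positions are expressed in the
    global ISB frame (``"global"``) or per-segment local frames
    (``"local"``).  ``welds`` lists rigid child->parent attachments that are
    not articulated joints (the patella rides with the tibia through the
    rigid patellar tendon).
    """

    segments: list[str]
    joints: list[JointDef]
    muscles: list[MusclePathDef]
    wrap_surfaces: list[WrapCylinder]
    skin_markers: LandmarkSet
    strength: dict[str, MuscleStrength]
    landmarks: LandmarkSet | None = None
    welds: list[tuple[str, str]] = field(default_factory=list)
    coordinates: str = "global"
    metadata: dict = field(default_factory=dict)

    def joint(self, name: str) -> JointDef:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(f"no joint {name!r}")

    def muscle(self, name: str) -> MusclePathDef:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(f"no muscle {name!r}")

    def wrap(self, name: str) -> WrapCylinder:
        for w in self.wrap_surfaces:
            if w.name == name:
                return w
        raise KeyError(f"no wrap surface {name!r}")

    def copy(self) -> "ModelGeometry":
        return load_model_dict(save_model_dict(self))

    def to_dict(self) -> dict:
        d = {
            "schema": SCHEMA_VERSION,
            "segments": list(self.segments),
            "joints": [j.to_dict() for j in self.joints],
            "muscles": [m.to_dict() for m in self.muscles],
            "wrap_surfaces": [w.to_dict() for w in self.wrap_surfaces],
            "skin_markers": self.skin_markers.to_dict(),
            "strength": {k: v.to_dict() for k, v in self.strength.items()},
            "landmarks": None if self.landmarks is None else self.landmarks.to_dict(),
            "welds": [list(w) for w in self.welds],
            "coordinates": self.coordinates,
            "metadata": self.metadata,
        }
        return d


def save_model_dict(m: ModelGeometry) -> dict:
    return m.to_dict()


def load_model_dict(d: Mapping) -> ModelGeometry:
    known = {"schema", "segments", "joints", "muscles", "wrap_surfaces",
             "skin_markers", "strength", "landmarks", "welds", "coordinates",
             "metadata"}
    schema = d.get("schema")
    if schema != SCHEMA_VERSION:
        raise ModelFormatError(f"unsupported model schema {schema!r}; expected {SCHEMA_VERSION}")
    extra = {k: d[k] for k in d if k not in known}
    if extra:
        warnings.warn(f"model file carries unknown fields (preserved): {sorted(extra)}")
    m = ModelGeometry(
        segments=list(d["segments"]),
        joints=[JointDef.from_dict(j) for j in d["joints"]],
        muscles=[MusclePathDef.from_dict(x) for x in d["muscles"]],
        wrap_surfaces=[WrapCylinder.from_dict(w) for w in d["wrap_surfaces"]],
        skin_markers=LandmarkSet.from_dict(d["skin_markers"]),
        strength={k: MuscleStrength.from_dict(v) for k, v in d["strength"].items()},
        landmarks=None if d.get("landmarks") is None else LandmarkSet.from_dict(d["landmarks"]),
        welds=[tuple(w) for w in d.get("welds", [])],
        coordinates=d.get("coordinates", "global"),
        metadata=dict(d.get("metadata", {})),
    )
    if extra:
        m.metadata.setdefault("_extra_fields", {}).update(extra)
    return m


def save_model(m: ModelGeometry, path: str | Path) -> None:
    """Write a model to JSON (schema version 1, UTF-8)."""
    path = Path(path)
    d = m.to_dict()
    extra = m.metadata.get("_extra_fields")
    if extra:
        d.update(extra)
        d["metadata"] = {k: v for k, v in m.metadata.items() if k != "_extra_fields"}
    path.write_text(json.dumps(d, indent=1), encoding="utf-8")


def load_model(path: str | Path) -> ModelGeometry:
    path = Path(path)
    try:
        d = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as e:
        raise ModelFormatError(f"cannot parse model JSON {path}: {e}") from e
    try:
        return load_model_dict(d)
    except (KeyError, TypeError) as e:
        raise ModelFormatError(f"malformed model file {path}: {e}") from e


# ---------------------------------------------------------------------------
# Template definition
# ---------------------------------------------------------------------------

@dataclass
class TemplateDefinition:
    """The homologous-landmark template: landmarks plus segment and tier maps."""

    landmarks: LandmarkSet
    segment_of: dict[str, str]
    tier_of: dict[str, str]
    muscle_points: dict[str, str] = field(default_factory=dict)

    def names_in_tier(self, tier: str) -> list[str]:
        return [n for n in self.landmarks.names if self.tier_of[n] == tier]

    def names_in_segment(self, segment: str) -> list[str]:
        return [n for n in self.landmarks.names if self.segment_of[n] == segment]


def _mirror_z(p: Sequence[float]) -> np.ndarray:
    q = np.asarray(p, float).copy()
    q[2] = -q[2]
    return q


def femur_landmark_positions(
    side: str,
    hip_center: np.ndarray | None = None,
    femur_length: float = 0.42,
    anteversion_deg: float = 12.0,
    neck_shaft_deg: float = 125.0,
    neck_length: float = 0.05,
    epicondyle_halfwidth: float = 0.045,
) -> dict[str, np.ndarray]:
    """Parametric femur landmark constructor (right side; left is mirrored).

    The shaft runs straight from the hip center to the knee center along -y,
    so the anatomical shaft coincides with the hip-knee biomechanical axis.
    The neck vector makes the given neck-shaft angle with the distal shaft in
    the frontal (y-z) plane and is then rotated about the shaft axis (+y) so
    that its transverse projection makes the anteversion angle with the
    posterior condylar axis, anterior tilt positive.
    """
    s = +1.0 if side == "r" else -1.0
    if hip_center is None:
        hip_center = np.array([0.0, -0.07, s * 0.09])
    hip_center = np.asarray(hip_center, float)
    knee_center = hip_center + np.array([0.0, -femur_length, 0.0])

    # Neck direction (base -> head) solved so that BOTH stated angles hold
    # exactly under the measurement definitions: the transverse projection
    # (x, z) makes the anteversion angle with the posterior condylar axis
    # (along z, condyles placed in the head's frontal plane x = const), and
    # the frontal projection (y, z) makes the neck-shaft angle with the
    # distal shaft vector (0, -1, 0).
    alpha = np.deg2rad(neck_shaft_deg - 90.0)   # frontal elevation above medial horizontal
    av = np.deg2rad(anteversion_deg)
    m = 1.0 / np.sqrt(1.0 + (np.cos(alpha) * np.tan(av)) ** 2)
    v = np.array([m * np.cos(alpha) * np.tan(av),   # anterior tilt
                  m * np.sin(alpha),                # superior
                  -s * m * np.cos(alpha)])          # medial

    head = hip_center
    neck_base = head - neck_length * v
    neck_mid = head - 0.5 * neck_length * v

    shaft = lambda f: hip_center + f * (knee_center - hip_center)
    lm = {
        "femoral_head_center": head,
        "femoral_neck_base": neck_base,
        "femoral_neck_mid": neck_mid,
        "greater_trochanter": hip_center + np.array([0.0, 0.005, s * 0.045]),
        "lesser_trochanter": hip_center + np.array([-0.01, -0.04, -s * 0.015]),
        "femur_shaft_25": shaft(0.25),
        "femur_shaft_mid": shaft(0.50),
        "femur_shaft_75": shaft(0.75),
        "femoral_epicondyle_med": knee_center + np.array([0.0, 0.0, -s * epicondyle_halfwidth]),
        "femoral_epicondyle_lat": knee_center + np.array([0.0, 0.0, s * epicondyle_halfwidth]),
        # posterior condyles lie in the head's frontal plane (same x) so the
        # frontal-plane and transverse-plane angle definitions are exact
        "femoral_condyle_med_post": knee_center + np.array([0.0, -0.01, -s * 0.035]),
        "femoral_condyle_lat_post": knee_center + np.array([0.0, -0.01, s * 0.035]),
        "femoral_condyle_med_dist": knee_center + np.array([0.0, -0.025, -s * 0.03]),
        "femoral_condyle_lat_dist": knee_center + np.array([0.0, -0.025, s * 0.03]),
        "patellar_groove": knee_center + np.array([0.03, 0.0, 0.0]),
        "linea_aspera_mid": shaft(0.5) + np.array([-0.025, 0.0, 0.0]),
        "gluteal_tuberosity": hip_center + np.array([-0.02, -0.06, s * 0.01]),
    }
    return {k: np.asarray(v, float) for k, v in lm.items()}


def tibia_landmark_positions(
    side: str,
    knee_center: np.ndarray | None = None,
    tibia_length: float = 0.40,
    torsion_deg: float = 15.0,
    condyle_halfwidth: float = 0.04,
    malleolus_halfwidth: float = 0.035,
) -> dict[str, np.ndarray]:
    """Parametric tibia/fibula landmark constructor.

    The tibial condylar axis lies along z at the plateau; the malleolar axis
    is the condylar axis rotated by the torsion angle about the tibial long
    axis, external torsion positive (lateral malleolus posterior).
    """
    s = +1.0 if side == "r" else -1.0
    if knee_center is None:
        knee_center = np.array([0.0, -0.49, s * 0.09])
    knee_center = np.asarray(knee_center, float)
    ankle_center = knee_center + np.array([0.0, -tibia_length, 0.0])

    # external torsion rotates the malleolar axis about the distal-pointing
    # tibial axis (-y) so that on the right the lateral malleolus moves posterior
    tau = np.deg2rad(s * torsion_deg)
    c, sn = np.cos(tau), np.sin(tau)
    rot = np.array([[c, 0.0, -sn], [0.0, 1.0, 0.0], [sn, 0.0, c]])  # about -y by tau
    mal_axis = rot @ np.array([0.0, 0.0, 1.0])

    shaft = lambda f: knee_center + f * (ankle_center - knee_center)
    lm = {
        "tibial_condyle_med": knee_center + np.array([0.0, -0.015, -s * condyle_halfwidth]),
        "tibial_condyle_lat": knee_center + np.array([0.0, -0.015, s * condyle_halfwidth]),
        "tibial_plateau_center": knee_center + np.array([0.0, -0.005, 0.0]),
        "tibial_tuberosity": knee_center + np.array([0.035, -0.04, 0.0]),
        "tibia_shaft_25": shaft(0.25),
        "tibia_shaft_mid": shaft(0.50),
        "tibia_shaft_75": shaft(0.75),
        "fibula_head": knee_center + np.array([-0.015, -0.02, s * 0.035]),
        "fibula_mid": shaft(0.5) + np.array([-0.005, 0.0, s * 0.03]),
        "fibula_distal": ankle_center + s * 1.15 * malleolus_halfwidth * mal_axis + np.array([0.0, 0.01, 0.0]),
        "soleal_line": shaft(0.3) + np.array([-0.02, 0.0, 0.0]),
        "tibia_distal_ant": ankle_center + np.array([0.02, 0.04, 0.0]),
        "medial_tibial_border_mid": shaft(0.5) + np.array([0.005, 0.0, -s * 0.03]),
        "malleolus_med": ankle_center - s * malleolus_halfwidth * mal_axis,
        "malleolus_lat": ankle_center + s * malleolus_halfwidth * mal_axis,
    }
    # mirror handling: for the left side the constructor above was written in
    # right-side sign conventions through `s`; torsion sign mirrors naturally.
    return {k: np.asarray(v, float) for k, v in lm.items()}


_PELVIS_MIDLINE_PRIMARY = {
    "pubic_symphysis_sup": (0.055, -0.09, 0.0),
}
_PELVIS_PAIRED_PRIMARY = {
    # ASIS and PSIS share the same height so the neutral pelvis frame is the
    # identity rotation (template built in the ISB pose)
    "ASIS": (0.08, 0.0, 0.12),
    "PSIS": (-0.07, 0.0, 0.04),
}
_PELVIS_MIDLINE_SECONDARY = {
    "torso_origin": (-0.05, 0.03, 0.0),
}
_PELVIS_PAIRED_SECONDARY = {
    "ischial_tuberosity": (-0.04, -0.125, 0.06),
    "iliac_crest_sup": (0.0, 0.10, 0.13),
    "ischium_inf": (-0.03, -0.145, 0.055),
    "iliac_crest_ant": (0.05, 0.08, 0.125),
    "iliac_crest_post": (-0.06, 0.07, 0.09),
    "iliac_blade_mid": (0.0, 0.05, 0.125),
    "acetabulum_rim_ant": (0.03, -0.06, 0.075),
    "acetabulum_rim_post": (-0.03, -0.065, 0.075),
    "acetabulum_rim_sup": (0.0, -0.035, 0.08),
    "ischial_spine": (-0.05, -0.09, 0.06),
    "obturator_foramen_sup": (0.02, -0.09, 0.05),
    "obturator_foramen_inf": (0.0, -0.12, 0.05),
    "pubic_tubercle": (0.055, -0.085, 0.025),
    "greater_sciatic_notch": (-0.055, -0.05, 0.07),
}

_FEMUR_PRIMARY = ("femoral_head_center", "femoral_epicondyle_med", "femoral_epicondyle_lat")
_TIBIA_PRIMARY = ("tibial_condyle_med", "tibial_condyle_lat", "malleolus_med", "malleolus_lat")
_PATELLA_PRIMARY = ("patella_apex",)

_PATELLA_LOCAL = {
    "patella_apex": (0.05, -0.02, 0.0),
    "patella_base": (0.05, 0.02, 0.0),
    "patella_med": (0.05, 0.0, -0.025),
    "patella_lat": (0.05, 0.0, 0.025),
}


def patella_landmark_positions(side: str, knee_center: np.ndarray | None = None) -> dict[str, np.ndarray]:
    s = +1.0 if side == "r" else -1.0
    if knee_center is None:
        knee_center = np.array([0.0, -0.49, s * 0.09])
    knee_center = np.asarray(knee_center, float)
    out = {}
    for name, (x, y, z) in _PATELLA_LOCAL.items():
        out[name] = knee_center + np.array([x, y + 0.02, s * z])
    return out


def build_template(
    femur_anteversion_deg: float = 12.0,
    femur_neck_shaft_deg: float = 125.0,
    tibia_torsion_deg: float = 15.0,
) -> TemplateDefinition:
    """Build the canonical 106-landmark bilateral template.

    21 primary landmarks (directly identifiable on MRI) and 85 secondary
    landmarks (to be projected by TPS), on a parametric simplified skeleton
    in ISB global coordinates, meters, neutral upright pose, exactly
    symmetric across the sagittal plane.  The anatomical landmark *names*
    and counts follow the published template structure; positions are a
    documented parametric stand-in.
    """
    names: list[str] = []
    coords: list[np.ndarray] = []
    segment_of: dict[str, str] = {}
    tier_of: dict[str, str] = {}

    def add(name: str, pos, segment: str, tier: str) -> None:
        names.append(name)
        coords.append(np.asarray(pos, float))
        segment_of[name] = segment
        tier_of[name] = tier

    # pelvis
    for name, pos in _PELVIS_MIDLINE_PRIMARY.items():
        add(name, pos, "pelvis", "primary")
    for name, pos in _PELVIS_PAIRED_PRIMARY.items():
        add(f"{name}_r", pos, "pelvis", "primary")
        add(f"{name}_l", _mirror_z(pos), "pelvis", "primary")
    for name, pos in _PELVIS_MIDLINE_SECONDARY.items():
        add(name, pos, "pelvis", "secondary")
    for name, pos in _PELVIS_PAIRED_SECONDARY.items():
        add(f"{name}_r", pos, "pelvis", "secondary")
        add(f"{name}_l", _mirror_z(pos), "pelvis", "secondary")

    # femora, patellae, tibiae
    for side in ("r", "l"):
        fl = femur_landmark_positions(side, anteversion_deg=femur_anteversion_deg,
                                      neck_shaft_deg=femur_neck_shaft_deg)
        for name, pos in fl.items():
            tier = "primary" if name in _FEMUR_PRIMARY else "secondary"
            add(f"{name}_{side}", pos, f"femur_{side}", tier)
        pl = patella_landmark_positions(side)
        for name, pos in pl.items():
            tier = "primary" if name in _PATELLA_PRIMARY else "secondary"
            add(f"{name}_{side}", pos, f"patella_{side}", tier)
        tl = tibia_landmark_positions(side, torsion_deg=tibia_torsion_deg)
        for name, pos in tl.items():
            tier = "primary" if name in _TIBIA_PRIMARY else "secondary"
            add(f"{name}_{side}", pos, f"tibia_{side}", tier)

    ls = LandmarkSet(names, np.array(coords), "ISB_global", "m")
    return TemplateDefinition(ls, segment_of, tier_of)


def add_joint_center_doubles(t: TemplateDefinition) -> TemplateDefinition:
    """Append the 4 hip/knee joint-center doubles (hip_r/l, knee_r/l).

    Each double copies the coordinates of the joint center already implied by
    the bone landmarks: the hip double duplicates the femoral head center;
    the knee double sits at the epicondyle midpoint.  Doubles let the joint
    center be expressed in both the parent and the child segment frame after
    segment separation.
    """
    if any(v == "joint_double" for v in t.tier_of.values()):
        raise ValueError("joint-center doubles already present")
    names = list(t.landmarks.names)
    coords = [t.landmarks.coords]
    segment_of = dict(t.segment_of)
    tier_of = dict(t.tier_of)
    new = []
    for side in ("r", "l"):
        hip = t.landmarks.get(f"femoral_head_center_{side}")
        knee = 0.5 * (t.landmarks.get(f"femoral_epicondyle_med_{side}")
                      + t.landmarks.get(f"femoral_epicondyle_lat_{side}"))
        new.append((f"hip_center_double_{side}", hip, "pelvis"))
        new.append((f"knee_center_double_{side}", knee, f"femur_{side}"))
    for name, pos, seg in new:
        names.append(name)
        coords.append(pos.reshape(1, 3))
        segment_of[name] = seg
        tier_of[name] = "joint_double"
    ls = LandmarkSet(names, np.vstack(coords), t.landmarks.frame, t.landmarks.units)
    return TemplateDefinition(ls, segment_of, tier_of, dict(t.muscle_points))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_model(m: ModelGeometry) -> list[str]:
    """Check all structural invariants; return a list of violation strings.

    Empty list means the model is well-formed.  Each violation names the
    offending element.
    """
    v: list[str] = []
    segs = set(m.segments)
    wraps = {w.name for w in m.wrap_surfaces}

    for j in m.joints:
        if j.parent_segment not in segs:
            v.append(f"joint {j.name}: unknown parent segment {j.parent_segment!r}")
        if j.child_segment not in segs:
            v.append(f"joint {j.name}: unknown child segment {j.child_segment!r}")
        n = np.linalg.norm(j.axis)
        if abs(n - 1.0) > 1e-8:
            v.append(f"joint {j.name}: axis norm {n:.6g} != 1")
        if not j.range[0] < j.range[1]:
            v.append(f"joint {j.name}: empty range {j.range}")
        if not np.all(np.isfinite(j.center_global)):
            v.append(f"joint {j.name}: non-finite center")

    for w in m.wrap_surfaces:
        if w.segment not in segs:
            v.append(f"wrap {w.name}: unknown segment {w.segment!r}")
        if not w.radius > 0:
            v.append(f"wrap {w.name}: radius {w.radius} not > 0")
        if not w.length > 0:
            v.append(f"wrap {w.name}: length {w.length} not > 0")
        n = np.linalg.norm(w.axis_dir)
        if abs(n - 1.0) > 1e-8:
            v.append(f"wrap {w.name}: axis_dir norm {n:.6g} != 1")

    seen = set()
    for mu in m.muscles:
        if mu.name in seen:
            v.append(f"muscle {mu.name}: duplicate name")
        seen.add(mu.name)
        for p in mu.points:
            if p.segment not in segs:
                v.append(f"muscle {mu.name} point {p.label}: unknown segment {p.segment!r}")
            if not np.all(np.isfinite(p.position)):
                v.append(f"muscle {mu.name} point {p.label}: non-finite position")
        for wname, i in mu.wraps:
            if wname not in wraps:
                v.append(f"muscle {mu.name}: unknown wrap surface {wname!r}")
            if not (0 <= i < len(mu.points) - 1):
                v.append(f"muscle {mu.name}: wrap segment index {i} out of range")
        for lbl, r in mu.search_radius_of.items():
            if not r > 0:
                v.append(f"muscle {mu.name}: search radius for {lbl!r} not > 0")

    for name, st in m.strength.items():
        if not st.max_isometric_force > 0:
            v.append(f"strength {name}: max_isometric_force not > 0")
        if not st.optimal_fiber_length > 0:
            v.append(f"strength {name}: optimal_fiber_length not > 0")

    for child, parent in m.welds:
        if child not in segs or parent not in segs:
            v.append(f"weld {child}->{parent}: unknown segment")

    return v
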