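"""Bone-geometry comparison measures.

Segment lengths (distances between adjacent joint centers), six pelvis
dimensions, three bone angles (femoral torsion, femoral neck-shaft, tibial
torsion), per-point location differences between two models, and
intra-observer landmark repeatability.

Angle definitions (all computed via atan2 of projected 2D components, which
is stable near 0 and 180 degrees):

femoral torsion (anteversion)
    angle between the femoral neck vector (neck base -> head center) and the
    posterior condylar vector, both projected onto the plane perpendicular
    to the hip-knee (biomechanical) femur axis.  Anteversion (neck anterior
    to the condylar axis) positive on the right limb, mirrored on the left.
neck-shaft angle
    angle between the femoral neck vector and the proximal shaft vector
    (25% femur length -> midshaft), both projected onto the frontal plane
    defined by the femoral head and the medial/lateral condyles; unsigned,
    in (0, 180) degrees.
tibial torsion
    angle between the tibial condylar vector and the malleolar vector, both
    projected onto the plane perpendicular to the knee-ankle tibial axis;
    external torsion positive on the right limb, mirrored on the left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LandmarkSet, ModelGeometry

MM = 1000.0


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"degenerate {what} (zero length)")
    return np.asarray(v, float) / n


def _project_out(v: np.ndarray, axis: np.ndarray, what: str) -> np.ndarray:
    """Project v onto the plane perpendicular to unit ``axis``."""
    p = v - np.dot(v, axis) * axis
    if np.linalg.norm(p) < 1e-12 * max(np.linalg.norm(v), 1e-30):
        raise ValueError(f"degenerate projection: {what} is parallel to the projection axis")
    return p


def _signed_angle_about(a: np.ndarray, b: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle (deg) from a to b about unit axis, right-hand positive."""
    return float(np.degrees(np.arctan2(np.dot(np.cross(a, b), axis), np.dot(a, b))))


# ---------------------------------------------------------------------------
# Lengths and pelvis dimensions
# ---------------------------------------------------------------------------

def segment_lengths(model: ModelGeometry, side: str = "r") -> dict[str, float]:
    """Femur and tibia lengths (m) from adjacent joint centers, plus the ratio."""
    if model.coordinates != "global":
        raise ValueError("segment_lengths expects a model in global coordinates")
    hip = model.joint(f"hip_{side}").center_global
    knee = model.joint(f"knee_{side}").center_global
    ankle = model.joint(f"ankle_{side}").center_global
    femur = float(np.linalg.norm(hip - knee))
    tibia = float(np.linalg.norm(knee - ankle))
    return {"femur_length": femur, "tibia_length": tibia,
            "femur_tibia_ratio": femur / tibia}


PELVIS_DIMENSIONS = ("ASIS_dist", "PSIS_dist", "Hip_dist", "IschTuber_dist",
                     "Pelv_Height", "Pelv_Depth")


def pelvis_dimensions(landmarks: LandmarkSet) -> dict[str, float]:
    """The six pelvis dimensions, in millimeters.

    ASIS distance, PSIS distance, hip-center distance, ischial-tuberosity
    distance, pelvis height (midpoint of superior ilia to midpoint of
    inferior ischia) and pelvis depth (superior pubic symphysis to the torso
    origin point).
    """
    ls = landmarks.to_m()

    def d(a, b):
        return float(np.linalg.norm(a - b)) * MM

    def mid(a, b):
        return 0.5 * (a + b)

    try:
        hip_r = ls.get("hip_center_double_r")
        hip_l = ls.get("hip_center_double_l")
    except KeyError:
        hip_r = ls.get("femoral_head_center_r")
        hip_l = ls.get("femoral_head_center_l")

    return {
        "ASIS_dist": d(ls.get("ASIS_r"), ls.get("ASIS_l")),
        "PSIS_dist": d(ls.get("PSIS_r"), ls.get("PSIS_l")),
        "Hip_dist": d(hip_r, hip_l),
        "IschTuber_dist": d(ls.get("ischial_tuberosity_r"), ls.get("ischial_tuberosity_l")),
        "Pelv_Height": d(mid(ls.get("iliac_crest_sup_r"), ls.get("iliac_crest_sup_l")),
                         mid(ls.get("ischium_inf_r"), ls.get("ischium_inf_l"))),
        "Pelv_Depth": d(ls.get("pubic_symphysis_sup"), ls.get("torso_origin")),
    }


# ---------------------------------------------------------------------------
# Bone angles
# ---------------------------------------------------------------------------

def femoral_torsion(landmarks: LandmarkSet, side: str = "r") -> float:
    """Femoral torsion (anteversion) in degrees, anteversion positive."""
    ls = landmarks.to_m()
    hip = ls.get(f"femoral_head_center_{side}")
    knee = 0.5 * (ls.get(f"femoral_epicondyle_med_{side}")
                  + ls.get(f"femoral_epicondyle_lat_{side}"))
    axis = _unit(hip - knee, "femur biomechanical axis")

    neck = hip - ls.get(f"femoral_neck_base_{side}")
    condyle = (ls.get(f"femoral_condyle_med_post_{side}")
               - ls.get(f"femoral_condyle_lat_post_{side}"))  # lateral -> medial
    neck_p = _project_out(neck, axis, "femoral neck vector")
    cond_p = _project_out(condyle, axis, "femoral condyle vector")
    # right limb: anteversion tilts the neck anterior of the condylar axis,
    # a rotation from the neck to the condylar vector about the proximal
    # axis; mirrored on the left.
    sign = 1.0 if side == "r" else -1.0
    return sign * _signed_angle_about(neck_p, cond_p, axis)


def neck_shaft_angle(landmarks: LandmarkSet, side: str = "r") -> float:
    """Femoral neck-shaft angle in degrees, unsigned, in (0, 180)."""
    ls = landmarks.to_m()
    head = ls.get(f"femoral_head_center_{side}")
    med = ls.get(f"femoral_condyle_med_post_{side}")
    lat = ls.get(f"femoral_condyle_lat_post_{side}")
    # frontal plane through head and both condyles
    normal = _unit(np.cross(med - head, lat - head), "frontal plane normal")

    neck = head - ls.get(f"femoral_neck_base_{side}")
    shaft = ls.get(f"femur_shaft_mid_{side}") - ls.get(f"femur_shaft_25_{side}")  # proximal -> distal
    neck_p = _project_out(neck, normal, "femoral neck vector")
    shaft_p = _project_out(shaft, normal, "proximal shaft vector")
    cosang = np.clip(np.dot(_unit(neck_p), _unit(shaft_p)), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def tibial_torsion(landmarks: LandmarkSet, side: str = "r") -> float:
    """Tibial torsion in degrees, external torsion positive."""
    ls = landmarks.to_m()
    knee = 0.5 * (ls.get(f"tibial_condyle_med_{side}") + ls.get(f"tibial_condyle_lat_{side}"))
    ankle = 0.5 * (ls.get(f"malleolus_med_{side}") + ls.get(f"malleolus_lat_{side}"))
    axis = _unit(knee - ankle, "tibial biomechanical axis")

    condyle = ls.get(f"tibial_condyle_lat_{side}") - ls.get(f"tibial_condyle_med_{side}")
    malleoli = ls.get(f"malleolus_lat_{side}") - ls.get(f"malleolus_med_{side}")
    cond_p = _project_out(condyle, axis, "tibial condyle vector")
    mal_p = _project_out(malleoli, axis, "malleoli vector")
    # external torsion carries the lateral malleolus posterior: on the right
    # this is a negative rotation from condylar to malleolar axis about the
    # proximal-pointing tibial axis.
    sign = -1.0 if side == "r" else 1.0
    return sign * _signed_angle_about(cond_p, mal_p, axis)


def bone_angles(landmarks: LandmarkSet, side: str = "r") -> dict[str, float]:
    return {
        "femoral_torsion": femoral_torsion(landmarks, side),
        "neck_shaft_angle": neck_shaft_angle(landmarks, side),
        "tibial_torsion": tibial_torsion(landmarks, side),
    }


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

@dataclass
class MeasureReport:
    """Per-measure values for two models plus absolute and percent differences.

    Percent differences follow the convention 100*(a - b)/a with ``a`` the
    reference (MRI-based) model value.
    """

    measures_a: dict[str, float]
    measures_b: dict[str, float] | None = None
    units: dict[str, str] = field(default_factory=dict)

    def differences(self) -> dict[str, dict[str, float]]:
        if self.measures_b is None:
            raise ValueError("no second model to compare")
        out = {}
        for k, a in self.measures_a.items():
            b = self.measures_b[k]
            out[k] = {"a": a, "b": b, "abs_diff": a - b,
                      "pct_diff": 100.0 * (a - b) / a if a != 0 else float("nan")}
        return out


def measure_model(model: ModelGeometry, landmarks: LandmarkSet | None = None) -> MeasureReport:
    """All scalar geometry measures of one model (lengths m, distances mm, angles deg)."""
    lm = landmarks if landmarks is not None else model.landmarks
    if lm is None:
        raise ValueError("model carries no landmarks and none were given")
    meas: dict[str, float] = {}
    units: dict[str, str] = {}
    for side in ("r", "l"):
        try:
            sl = segment_lengths(model, side)
        except KeyError:
            continue
        for k, v in sl.items():
            meas[f"{k}_{side}"] = v
            units[f"{k}_{side}"] = "m" if "ratio" not in k else ""
    for k, v in pelvis_dimensions(lm).items():
        meas[k] = v
        units[k] = "mm"
    for side in ("r", "l"):
        for k, v in bone_angles(lm, side).items():
            meas[f"{k}_{side}"] = v
            units[f"{k}_{side}"] = "deg"
    return MeasureReport(meas, units=units)


def point_differences(model_a: ModelGeometry, model_b: ModelGeometry) -> dict:
    """Euclidean distances (mm) between homologous muscle path points.

    Both models must be localized to segment frames so that the comparison is
    independent of global pose.  Returns per-point distances grouped by
    muscle, plus overall mean and SD.
    """
    if model_a.coordinates != "local" or model_b.coordinates != "local":
        raise ValueError("point_differences expects localized models")
    names_a = {(m.name, p.label) for m in model_a.muscles for p in m.points}
    names_b = {(m.name, p.label) for m in model_b.muscles for p in m.points}
    if names_a != names_b:
        raise ValueError(f"muscle point sets differ: {sorted(names_a ^ names_b)}")

    per_muscle: dict[str, dict[str, float]] = {}
    all_d = []
    for mu_a in model_a.muscles:
        mu_b = model_b.muscle(mu_a.name)
        group = {}
        for p_a in mu_a.points:
            p_b = mu_b.point(p_a.label)
            if p_a.segment != p_b.segment:
                raise ValueError(
                    f"point {mu_a.name}/{p_a.label}: segment mismatch "
                    f"{p_a.segment} vs {p_b.segment}")
            dist = float(np.linalg.norm(p_a.position - p_b.position)) * MM
            group[p_a.label] = dist
            all_d.append(dist)
        per_muscle[mu_a.name] = group
    arr = np.asarray(all_d)
    return {"per_muscle": per_muscle,
            "mean_mm": float(arr.mean()), "sd_mm": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0}


def landmark_repeatability(sessions: list[LandmarkSet]) -> dict:
    """Intra-observer repeatability across digitization sessions.

    For every landmark, the mean pairwise distance between sessions; summary
    mean +/- SD over landmarks (mm), plus per-subgroup summaries keyed by
    landmark-name substring (e.g. ``patella``).
    """
    if len(sessions) < 2:
        raise ValueError("need >= 2 sessions")
    names = sessions[0].names
    for s in sessions[1:]:
        if s.names != names:
            raise ValueError("sessions carry different landmark name sets")
    stacks = np.stack([s.to_mm().coords for s in sessions])  # (S, N, 3)
    S = len(sessions)
    per_landmark = {}
    for i, name in enumerate(names):
        ds = [np.linalg.norm(stacks[a, i] - stacks[b, i])
              for a in range(S) for b in range(a + 1, S)]
        per_landmark[name] = float(np.mean(ds))
    vals = np.asarray(list(per_landmark.values()))
    out = {"per_landmark_mm": per_landmark,
           "mean_mm": float(vals.mean()),
           "sd_mm": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
           "subgroups": {}}
    for key in ("patella", "pelvis", "femur", "tibia"):
        sub = [v for n, v in per_landmark.items() if key in n.lower()]
        if sub:
            a = np.asarray(sub)
            out["subgroups"][key] = {"mean_mm": float(a.mean()),
                                     "sd_mm": float(a.std(ddof=1)) if len(a) > 1 else 0.0}
    return out
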