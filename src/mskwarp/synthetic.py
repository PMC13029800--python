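"""Synthetic fixtures: the simplified model, synthetic participants, and
reference waveforms.

Everything here is generated deterministically from a seed, so every pipeline
stage is testable without any imaging or motion-capture downloads.

The fixture model is a simplified bilateral lower-limb model (pelvis, femora,
patellae, tibiae, feet; hinge hips, knees and ankles; 12 muscles with via
points; wrap cylinders at the knees for the quadriceps and at the hips for
psoas).  Synthetic participants are smooth non-affine deformations of the
template landmark constellation — a random quadratic polynomial field plus a
small-amplitude thin-plate spline driven by a few control-point
perturbations — with optional isotropic Gaussian digitization noise (default
sigma 2.0 mm, matching the magnitude of reported intra-observer landmark
repeatability) and an optional deterministic "sex effect" that widens the
pelvis while shortening the femora.

Because the random warps are low-order (polynomial degree <= 2 plus <= 8 TPS
control perturbations), the ground-truth deformation stays within the family
representable by the fitted spline, so sub-millimeter recovery is an
achievable bar rather than an accident of luck.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (LandmarkSet, ModelGeometry, MusclePathDef, MusclePathPoint,
                   MuscleStrength, JointDef, WrapCylinder, TemplateDefinition,
                   build_template, add_joint_center_doubles)
from .frames import build_frames
from .tps import fit_tps, apply_tps, TpsTransform
from .muscle_mech import moment_arm, joint_grid, MomentArmWaveform


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_participants: int = 8
    warp_amplitude: float = 0.010        # m, peak smooth non-affine deformation
    landmark_noise_sigma: float = 2.0    # mm, digitization noise
    sex_effect: float = 0.0              # scale of the pelvis-width/femur-length mode
    scale_range: tuple[float, float] = (0.95, 1.05)

    def __post_init__(self) -> None:
        if self.warp_amplitude < 0 or self.landmark_noise_sigma < 0:
            raise ValueError("amplitudes must be >= 0")


# ---------------------------------------------------------------------------
# Fixture model
# ---------------------------------------------------------------------------

def _hinge(name, parent, child, center, rng_lo_deg, rng_hi_deg):
    return JointDef(name, parent, child, center, np.array([0.0, 0.0, 1.0]),
                    (np.deg2rad(rng_lo_deg), np.deg2rad(rng_hi_deg)))


def _mk_muscle(name, pts, wraps=(), radii=None):
    points = [MusclePathPoint(lbl, seg, np.asarray(pos, float), role)
              for (lbl, seg, pos, role) in pts]
    return MusclePathDef(name, points, list(wraps), dict(radii or {}))


_STRENGTH = {
    "psoas": (1500.0, 0.10), "rectus_femoris": (1500.0, 0.075),
    "vastus_lateralis": (2500.0, 0.08), "vastus_medialis": (1500.0, 0.08),
    "gluteus_maximus_med": (1500.0, 0.15), "gluteus_medius": (2000.0, 0.07),
    "tensor_fasciae_latae": (400.0, 0.10), "sartorius": (250.0, 0.40),
    "adductor_magnus_dist": (1000.0, 0.13), "biceps_femoris": (1000.0, 0.10),
    "gastrocnemius_medialis": (1500.0, 0.06), "soleus": (3500.0, 0.05),
}


def make_fixture_model(template: TemplateDefinition | None = None) -> ModelGeometry:
    """Deterministic simplified bilateral lower-limb model in ISB global meters.

    Right-side muscles only (12), hinge hips/knees/ankles on both sides, a
    knee wrap cylinder for the quadriceps and a hip wrap cylinder for psoas.
    Passes :func:`mskwarp.core.validate_model`.
    """
    t = template or add_joint_center_doubles(build_template())
    ls = t.landmarks

    def L(name):
        return ls.get(name)

    joints = []
    for side in ("r", "l"):
        hip = L(f"femoral_head_center_{side}")
        knee = 0.5 * (L(f"femoral_epicondyle_med_{side}") + L(f"femoral_epicondyle_lat_{side}"))
        ankle = 0.5 * (L(f"malleolus_med_{side}") + L(f"malleolus_lat_{side}"))
        joints += [
            _hinge(f"hip_{side}", "pelvis", f"femur_{side}", hip, -30, 120),
            _hinge(f"knee_{side}", f"femur_{side}", f"tibia_{side}", knee, -120, 10),
            _hinge(f"ankle_{side}", f"tibia_{side}", f"foot_{side}", ankle, -40, 40),
        ]

    hip = L("femoral_head_center_r")
    knee = 0.5 * (L("femoral_epicondyle_med_r") + L("femoral_epicondyle_lat_r"))
    ankle = 0.5 * (L("malleolus_med_r") + L("malleolus_lat_r"))

    wraps = [
        WrapCylinder("knee_cyl_r", "femur_r", knee + np.array([0.005, 0.0, 0.0]),
                     np.array([0.0, 0.0, 1.0]), radius=0.025, length=0.10,
                     active_quadrant="+x"),
        WrapCylinder("hip_cyl_r", "pelvis", hip + np.array([0.015, 0.01, 0.0]),
                     np.array([0.0, 0.0, 1.0]), radius=0.015, length=0.06,
                     active_quadrant="+x"),
    ]

    z = 0.09  # right-limb lateral offset of the long axis
    muscles = [
        _mk_muscle("psoas", [
            ("origin", "pelvis", (-0.02, 0.05, 0.03), "origin"),
            ("P1", "pelvis", (0.035, -0.055, 0.07), "via"),
            ("insertion", "femur_r", L("lesser_trochanter_r"), "insertion"),
        ], wraps=[("hip_cyl_r", 1)], radii={"P1": 0.02}),
        _mk_muscle("rectus_femoris", [
            ("origin", "pelvis", (0.045, -0.04, 0.08), "origin"),
            ("P1", "femur_r", (0.042, -0.30, z), "via"),
            ("insertion", "patella_r", L("patella_base_r"), "insertion"),
        ], wraps=[("knee_cyl_r", 1)], radii={"P1": 0.005, "insertion": 0.005}),
        _mk_muscle("vastus_lateralis", [
            ("origin", "femur_r", (0.01, -0.15, 0.115), "origin"),
            ("P1", "femur_r", (0.042, -0.40, 0.105), "via"),
            ("insertion", "patella_r", L("patella_lat_r"), "insertion"),
        ], wraps=[("knee_cyl_r", 1)], radii={"P1": 0.005, "insertion": 0.005}),
        _mk_muscle("vastus_medialis", [
            ("origin", "femur_r", (0.01, -0.20, 0.068), "origin"),
            ("P1", "femur_r", (0.042, -0.41, 0.072), "via"),
            ("insertion", "patella_r", L("patella_med_r"), "insertion"),
        ], wraps=[("knee_cyl_r", 1)], radii={"P1": 0.005, "insertion": 0.005}),
        _mk_muscle("gluteus_maximus_med", [
            ("origin", "pelvis", (-0.07, 0.02, 0.06), "origin"),
            ("P1", "pelvis", (-0.06, -0.09, 0.11), "via"),
            ("insertion", "femur_r", L("gluteal_tuberosity_r"), "insertion"),
        ], radii={"P1": 0.02}),
        _mk_muscle("gluteus_medius", [
            ("origin", "pelvis", (-0.01, 0.05, 0.12), "origin"),
            ("insertion", "femur_r", L("greater_trochanter_r"), "insertion"),
        ]),
        _mk_muscle("tensor_fasciae_latae", [
            ("origin", "pelvis", (0.07, -0.01, 0.115), "origin"),
            ("P1", "femur_r", (0.02, -0.25, 0.125), "via"),
            ("insertion", "tibia_r", (0.005, -0.52, 0.12), "insertion"),
        ], radii={"P1": 0.01}),
        _mk_muscle("sartorius", [
            ("origin", "pelvis", (0.075, -0.005, 0.11), "origin"),
            ("P1", "femur_r", (0.02, -0.35, 0.05), "via"),
            ("P2", "femur_r", (0.0, -0.47, 0.04), "via"),
            ("insertion", "tibia_r", (0.015, -0.55, 0.06), "insertion"),
        ], radii={"P1": 0.015, "P2": 0.01}),
        _mk_muscle("adductor_magnus_dist", [
            ("origin", "pelvis", (-0.04, -0.12, 0.055), "origin"),
            ("insertion", "femur_r", (0.0, -0.45, 0.06), "insertion"),
        ]),
        _mk_muscle("biceps_femoris", [
            ("origin", "pelvis", L("ischial_tuberosity_r"), "origin"),
            ("insertion", "tibia_r", L("fibula_head_r"), "insertion"),
        ]),
        _mk_muscle("gastrocnemius_medialis", [
            ("origin", "femur_r", (-0.025, -0.47, 0.06), "origin"),
            ("P1", "tibia_r", (-0.03, -0.60, 0.08), "via"),
            ("insertion", "foot_r", (-0.045, -0.92, 0.085), "insertion"),
        ], radii={"P1": 0.01}),
        _mk_muscle("soleus", [
            ("origin", "tibia_r", (-0.02, -0.55, 0.095), "origin"),
            ("insertion", "foot_r", (-0.045, -0.92, 0.09), "insertion"),
        ]),
    ]

    marker_names = []
    marker_pos = []
    marker_spec = {
        "RASI": L("ASIS_r") + [0.01, 0, 0.01], "LASI": L("ASIS_l") + [0.01, 0, -0.01],
        "RPSI": L("PSIS_r") + [-0.01, 0, 0], "LPSI": L("PSIS_l") + [-0.01, 0, 0],
        "RTHI": (0.03, -0.30, 0.13), "LTHI": (0.03, -0.30, -0.13),
        "RKNE": L("femoral_epicondyle_lat_r") + [0, 0, 0.02],
        "LKNE": L("femoral_epicondyle_lat_l") + [0, 0, -0.02],
        "RTIB": (0.02, -0.65, 0.12), "LTIB": (0.02, -0.65, -0.12),
        "RANK": L("malleolus_lat_r") + [0, 0, 0.01],
        "LANK": L("malleolus_lat_l") + [0, 0, -0.01],
        "RHEE": (-0.06, -0.92, 0.09), "LHEE": (-0.06, -0.92, -0.09),
        "RTOE": (0.15, -0.94, 0.10), "LTOE": (0.15, -0.94, -0.10),
    }
    for k, v in marker_spec.items():
        marker_names.append(k)
        marker_pos.append(np.asarray(v, float))
    markers = LandmarkSet(marker_names, np.array(marker_pos), "ISB_global", "m")

    strength = {k: MuscleStrength(*v) for k, v in _STRENGTH.items()}

    model = ModelGeometry(
        segments=["pelvis", "femur_r", "femur_l", "patella_r", "patella_l",
                  "tibia_r", "tibia_l", "foot_r", "foot_l"],
        joints=joints,
        muscles=muscles,
        wrap_surfaces=wraps,
        skin_markers=markers,
        strength=strength,
        landmarks=ls.copy(),
        welds=[("patella_r", "tibia_r"), ("patella_l", "tibia_l")],
        coordinates="global",
        metadata={"fixture": True},
    )
    frames = build_frames(ls)
    for j in model.joints:
        j.center_in_parent = frames[j.parent_segment].to_local(j.center_global)
        j.center_in_child = frames[j.child_segment].to_local(j.center_global)
    return model


# ---------------------------------------------------------------------------
# Synthetic participants
# ---------------------------------------------------------------------------

def _sex_effect_field(points: np.ndarray, scale: float) -> np.ndarray:
    """Deterministic pelvis-width / femur-length covariation mode.

    Positive ``scale`` widens the pelvis (pushes points laterally outward in
    the pelvic band) and shortens the femora (compresses the thigh band
    toward the hip level); negative scale does the opposite.
    """
    out = np.zeros_like(points)
    y = points[:, 1]
    z = points[:, 2]
    # pelvic band: y > -0.2 -> lateral widening proportional to |z|
    pelvic = np.clip((y + 0.20) / 0.25, 0.0, 1.0)
    out[:, 2] += scale * 0.04 * pelvic * z / 0.12
    # thigh band: -0.55 < y < -0.05 -> vertical compression toward hip level
    thigh = np.clip((-0.05 - y) / 0.50, 0.0, 1.0) * np.clip((y + 0.95) / 0.40, 0.0, 1.0)
    out[:, 1] += scale * 0.03 * thigh
    return out


def generic_proportions_bias(points: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Deterministic deformation emulating generic-model proportions.

    Generic templates systematically differ from adult anatomy: a narrower
    inter-ischial spacing and a relatively shorter femur with a longer
    tibia.  Applying this field to the template produces a "generic-scaled"
    stand-in whose contrast with personalized shapes is a single systematic
    mode, as seen when personalized and generic models are pooled in one
    shape PCA.
    """
    pts = np.asarray(points, float)
    out = pts.copy()
    y, z = pts[:, 1], pts[:, 2]
    pelvic = np.clip((y + 0.20) / 0.25, 0.0, 1.0)
    out[:, 2] -= scale * 0.03 * pelvic * z / 0.12          # narrow the pelvis
    thigh = np.clip((-0.05 - y) / 0.45, 0.0, 1.0) * np.clip((y + 0.55) / 0.50, 0.0, 1.0)
    out[:, 1] += scale * 0.025 * thigh                      # shorten the femur
    shank = np.clip((-0.49 - y) / 0.40, 0.0, 1.0)
    out[:, 1] -= scale * 0.02 * shank                       # lengthen the tibia
    return out


@dataclass
class GroundTruthWarp:
    """The smooth deformation used to create one synthetic participant."""

    poly_coeffs: np.ndarray      # (10, 3) quadratic polynomial field
    tps: TpsTransform | None
    sex_scale: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        out = _poly_eval(pts, self.poly_coeffs)
        if self.tps is not None:
            out = out + (apply_tps(self.tps, pts) - pts)
        if self.sex_scale != 0.0:
            out = out + _sex_effect_field(pts, self.sex_scale)
        return out


def _poly_basis(pts: np.ndarray) -> np.ndarray:
    x, y, z = pts.T
    return np.stack([np.ones_like(x), x, y, z, x * y, x * z, y * z,
                     x * x, y * y, z * z], axis=1)


def _poly_eval(pts: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    return _poly_basis(pts) @ coeffs


def make_participant(
    template: TemplateDefinition,
    cfg: SyntheticConfig,
    idx: int = 0,
) -> tuple[LandmarkSet, GroundTruthWarp]:
    """One synthetic participant: warped template landmarks + ground truth.

    The deformation is affine (uniform scale drawn from ``scale_range`` plus
    small random linear mixing) + random quadratic terms + a small TPS bump
    field from 8 control points, scaled so the peak non-affine displacement
    over the landmarks is ``warp_amplitude``; isotropic Gaussian noise of
    ``landmark_noise_sigma`` mm is added last.  The sex-effect mode is added
    with sign +1 for even ``idx`` and -1 for odd when ``sex_effect`` > 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, idx]))
    pts = template.landmarks.to_m().coords
    n = pts.shape[0]

    # affine part: uniform scale plus linear mixing / translation whose size
    # is tied to the warp amplitude (zero amplitude -> pure scale)
    scale = rng.uniform(*cfg.scale_range)
    A = scale * (np.eye(3) + rng.normal(scale=2.0 * cfg.warp_amplitude, size=(3, 3)))
    b = rng.normal(scale=cfg.warp_amplitude, size=3)

    coeffs = np.zeros((10, 3))
    coeffs[0] = b
    coeffs[1:4] = A.T
    # quadratic terms, scaled to a fraction of the warp amplitude over the cloud
    quad = rng.normal(size=(6, 3))
    span = np.abs(_poly_basis(pts)[:, 4:]).max()
    if cfg.warp_amplitude > 0 and span > 0:
        quad *= 0.5 * cfg.warp_amplitude / (span * np.abs(quad).max())
        coeffs[4:] = quad

    tps_gt = None
    if cfg.warp_amplitude > 0:
        ctrl_idx = rng.choice(n, size=8, replace=False)
        ctrl = pts[ctrl_idx]
        bump = rng.normal(size=(8, 3))
        bump *= 0.5 * cfg.warp_amplitude / np.abs(bump).max()
        tps_gt = fit_tps(ctrl, ctrl + bump, 0.0)

    sex_scale = 0.0
    if cfg.sex_effect > 0:
        sex_scale = cfg.sex_effect * (1.0 if idx % 2 == 0 else -1.0)

    gt = GroundTruthWarp(coeffs, tps_gt, sex_scale)
    warped = gt.apply(pts)
    if cfg.landmark_noise_sigma > 0:
        warped = warped + rng.normal(scale=cfg.landmark_noise_sigma / 1000.0, size=warped.shape)
    ls = LandmarkSet(list(template.landmarks.names), warped, "ISB_global", "m")
    return ls, gt


def make_cohort(cfg: SyntheticConfig, template: TemplateDefinition | None = None):
    """List of (participant landmarks, ground truth) pairs."""
    t = template or add_joint_center_doubles(build_template())
    return t, [make_participant(t, cfg, i) for i in range(cfg.n_participants)]


# ---------------------------------------------------------------------------
# Reference waveforms
# ---------------------------------------------------------------------------

def make_reference_waveforms(model: ModelGeometry, joints: list[str] | None = None,
                             n_grid: int = 61) -> dict[str, dict[str, MomentArmWaveform]]:
    """Moment-arm waveforms of the unperturbed fixture for every muscle that
    spans each joint, on a fixed ``n_grid``-point grid over the joint range.

    Returns ``{joint: {muscle: waveform}}``; muscles with everywhere-zero
    moment arm about a joint are omitted.
    """
    joints = joints or [j.name for j in model.joints]
    out: dict[str, dict[str, MomentArmWaveform]] = {}
    for jname in joints:
        j = model.joint(jname)
        grid = joint_grid(j, n_grid)
        per = {}
        for mu in model.muscles:
            wf = moment_arm(model, mu.name, jname, grid)
            if np.max(np.abs(wf.values)) > 1e-6:
                per[mu.name] = wf
        out[jname] = per
    return out
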