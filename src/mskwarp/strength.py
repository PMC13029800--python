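"""Generic linear scaling and maximum-isometric-force scaling.

Linear scaling stretches segment geometry by per-segment factors derived
from marker-pair distances (participant / generic), as in conventional
marker-based model scaling.  Maximum isometric force is then adjusted on the
premise that force capacity is proportional to physiological cross-sectional
area (PCSA = volume / optimal fiber length):

    factor = (V_scaled / V_generic) / (l_opt_scaled / l_opt_generic)

with total lower-limb muscle volume predicted from anthropometry by the
linear regression

    V [cm^3] = 47 * mass [kg] * height [m] + 1285

and allocated to individual muscles in proportion to the generic model's
per-muscle volume fractions.  The regression constants are unit-bound:
mass in kilograms, height in meters, volume in cubic centimeters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LandmarkSet, ModelGeometry
from .frames import build_frames, localize, globalize


@dataclass
class AnthropometrySpec:
    mass: float         # kg
    body_height: float  # m

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.body_height <= 0:
            raise ValueError("mass and body height must be > 0")


@dataclass
class MuscleStrengthSpec:
    muscle: str
    V_generic: float          # cm^3 (or any consistent volume unit)
    V_scaled: float
    l_optimal_generic: float  # m
    l_optimal_scaled: float
    F_max: float              # N, generic maximum isometric force

    def __post_init__(self) -> None:
        for f in ("V_generic", "V_scaled", "l_optimal_generic", "l_optimal_scaled", "F_max"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{self.muscle}: {f} must be > 0")


@dataclass
class ScaleSet:
    """Per-segment (sx, sy, sz) scale factors."""

    factors: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        for seg, f in self.factors.items():
            if any(v <= 0 for v in f):
                raise ValueError(f"segment {seg}: non-positive scale factor {f}")

    def mean_factor(self, segment: str) -> float:
        return float(np.mean(self.factors[segment]))


def handsfield_volume(a: AnthropometrySpec) -> float:
    """Total lower-limb muscle volume (cm^3) from mass (kg) and height (m)."""
    return 47.0 * a.mass * a.body_height + 1285.0


def strength_scale_factor(s: MuscleStrengthSpec) -> float:
    """PCSA-based maximum-isometric-force scaling factor (dimensionless)."""
    return (s.V_scaled / s.V_generic) / (s.l_optimal_scaled / s.l_optimal_generic)


def linear_scale_factors(
    generic_markers: LandmarkSet,
    participant_markers: LandmarkSet,
    pair_spec: dict[str, list[tuple[str, str]]],
) -> ScaleSet:
    """Per-segment scale factors from marker-pair distance ratios.

    ``pair_spec`` maps segment -> list of (marker_a, marker_b) pairs; the
    factor is the mean over pairs of participant distance / generic distance,
    applied isotropically (sx = sy = sz) as the default.
    """
    g = generic_markers.to_m()
    p = participant_markers.to_m()
    factors = {}
    for seg, pairs in pair_spec.items():
        ratios = []
        for a, b in pairs:
            dg = float(np.linalg.norm(g.get(a) - g.get(b)))
            dp = float(np.linalg.norm(p.get(a) - p.get(b)))
            if dg <= 0:
                raise ValueError(f"segment {seg}: zero generic distance for pair ({a}, {b})")
            ratios.append(dp / dg)
        f = float(np.mean(ratios))
        factors[seg] = (f, f, f)
    return ScaleSet(factors)


DEFAULT_PAIR_SPEC: dict[str, list[tuple[str, str]]] = {
    # stand-in marker pairs per segment for the fixture marker set
    "pelvis": [("RASI", "LASI"), ("RPSI", "LPSI")],
    "femur_r": [("RASI", "RKNE")],
    "femur_l": [("LASI", "LKNE")],
    "tibia_r": [("RKNE", "RANK")],
    "tibia_l": [("LKNE", "LANK")],
    "patella_r": [("RASI", "RKNE")],
    "patella_l": [("LASI", "LKNE")],
    "foot_r": [("RHEE", "RTOE")],
    "foot_l": [("LHEE", "LTOE")],
}


def apply_linear_scaling(model: ModelGeometry, s: ScaleSet) -> ModelGeometry:
    """Scale each segment's local geometry componentwise; fiber lengths scale
    with the segment mean factor of the muscle's origin segment.

    The model is localized to segment frames, scaled, and re-globalized with
    joint-center translations propagated down the chain so segments stay
    connected (the parent's joint center defines the child's position).
    """
    if model.coordinates != "global":
        raise ValueError("apply_linear_scaling expects a global-coordinates model")
    if model.landmarks is None:
        raise ValueError("model must carry landmarks to build frames for scaling")
    frames = build_frames(model.landmarks, model.segments)
    local = localize(model, frames)

    def seg_factors(seg: str) -> np.ndarray:
        return np.asarray(s.factors.get(seg, (1.0, 1.0, 1.0)), float)

    for mu in local.muscles:
        for p in mu.points:
            p.position = p.position * seg_factors(p.segment)
    for j in local.joints:
        j.center_in_parent = j.center_in_parent * seg_factors(j.parent_segment)
        j.center_in_child = j.center_in_child * seg_factors(j.child_segment)
    for w in local.wrap_surfaces:
        w.axis_point = w.axis_point * seg_factors(w.segment)

    # rebuild global geometry: walk the chain root-down, shifting each child
    # frame's origin so its (scaled) joint center stays coincident with the
    # parent's (scaled) center — segments remain connected after scaling
    new_frames = {seg: f for seg, f in frames.items()}
    joint_to = {j.child_segment: j for j in local.joints}
    weld_to = dict(local.welds)
    for seg in _topo_order(model):
        if seg in joint_to:
            j = joint_to[seg]
            pf, cf = new_frames[j.parent_segment], new_frames[seg]
            center = pf.to_global(j.center_in_parent)      # already scaled
            new_origin = center - cf.R.T @ j.center_in_child
            new_frames[seg] = type(cf)(seg, new_origin, cf.R.copy())
        elif seg in weld_to:
            # welded segments keep their offset relative to the weld parent
            pf_old, pf_new = frames[weld_to[seg]], new_frames[weld_to[seg]]
            cf = new_frames[seg]
            new_origin = cf.origin + (pf_new.origin - pf_old.origin)
            new_frames[seg] = type(cf)(seg, new_origin, cf.R.copy())

    out = globalize(local, new_frames)
    for mu_name, st in out.strength.items():
        mu = _muscle_or_none(out, mu_name)
        if mu is None:
            continue
        st.optimal_fiber_length *= _fiber_scale(mu, s)
    out.metadata.setdefault("linear_scaling", {})["factors"] = {
        k: list(v) for k, v in s.factors.items()}
    return out


def _fiber_scale(mu, s: ScaleSet) -> float:
    """Geometric mean of the mean scale factors of the segments the muscle spans."""
    segs = sorted({p.segment for p in mu.points})
    vals = [s.mean_factor(seg) if seg in s.factors else 1.0 for seg in segs]
    return float(np.exp(np.mean(np.log(vals))))


def _muscle_or_none(model: ModelGeometry, name: str):
    try:
        return model.muscle(name)
    except KeyError:
        return None


def _topo_order(model: ModelGeometry) -> list[str]:
    parent_of = {j.child_segment: j.parent_segment for j in model.joints}
    parent_of.update({c: p for c, p in model.welds})
    order, seen = [], set()

    def visit(seg):
        if seg in seen:
            return
        if seg in parent_of:
            visit(parent_of[seg])
        seen.add(seg)
        order.append(seg)

    for seg in model.segments:
        visit(seg)
    return order


# ---------------------------------------------------------------------------
# Strength scaling from anthropometry
# ---------------------------------------------------------------------------

def apply_strength_scaling(
    model: ModelGeometry,
    a: AnthropometrySpec,
    generic_anthro: AnthropometrySpec,
    generic_fractions: dict[str, float] | None = None,
    scaled_fiber_lengths: dict[str, float] | None = None,
) -> ModelGeometry:
    """Scale every muscle's maximum isometric force from anthropometry.

    Total lower-limb volume for the participant and the generic model come
    from the volume regression; per-muscle volumes are allocated with the
    generic model's volume fractions (uniform fractions if none given), so
    the volume ratio is identical across muscles.  The fiber-length ratio
    uses ``scaled_fiber_lengths`` when given (else the model's current
    values, i.e. ratio 1).
    """
    out = model.copy()
    V_generic_total = handsfield_volume(generic_anthro)
    V_scaled_total = handsfield_volume(a)
    muscles = list(out.strength)
    if generic_fractions is None:
        generic_fractions = {mname: 1.0 / len(muscles) for mname in muscles}
    missing = [mname for mname in muscles if mname not in generic_fractions]
    if missing:
        raise ValueError(f"no generic volume fraction for muscles: {missing}")

    factors = {}
    for mname in muscles:
        st = out.strength[mname]
        l_gen = st.optimal_fiber_length
        l_scl = (scaled_fiber_lengths or {}).get(mname, l_gen)
        spec = MuscleStrengthSpec(
            muscle=mname,
            V_generic=generic_fractions[mname] * V_generic_total,
            V_scaled=generic_fractions[mname] * V_scaled_total,
            l_optimal_generic=l_gen,
            l_optimal_scaled=l_scl,
            F_max=st.max_isometric_force,
        )
        k = strength_scale_factor(spec)
        st.max_isometric_force *= k
        st.optimal_fiber_length = l_scl
        factors[mname] = k
    out.metadata.setdefault("strength_scaling", {}).update(
        {"V_generic_cm3": V_generic_total, "V_scaled_cm3": V_scaled_total,
         "factors": factors})
    return out
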