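"""ISB anatomical segment frames: construction and local/global transforms.

After warping, landmarks and muscle points are separated into segments and
each segment is expressed in its own ISB-style anatomical frame (x anterior,
y superior, z right/lateral).  The frame recipes:

pelvis
    origin at the ASIS midpoint; z along ASIS_l -> ASIS_r; x anterior,
    orthogonal to z within the plane through the ASIS midpoint and the PSIS
    midpoint; y = z cross x.
femur
    origin at the hip (femoral head) center; y from the knee center
    (epicondyle midpoint) toward the hip center; z toward the lateral
    epicondyle, orthogonalized against y; x = y cross z.
tibia
    origin at the knee center (tibial condyle midpoint); y from the ankle
    center (malleolus midpoint) toward the knee center; z toward the lateral
    condyle, orthogonalized; x = y cross z.
patella
    origin at the apex; y from apex to base; z toward the lateral border,
    orthogonalized; x = y cross z.
foot
    no dedicated bone landmarks exist in the template; the foot frame reuses
    the tibia's rotation translated to the ankle center (documented
    simplification; the foot only carries distal muscle insertions).

In each recipe the primary axis is kept exact and the secondary axis is
orthogonalized against it (Gram-Schmidt); all rotations are proper
(det = +1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LandmarkSet, ModelGeometry


@dataclass
class SegmentFrame:
    """A segment's anatomical frame: global origin and global->local rotation.

    Local coordinates of a global point p are ``R @ (p - origin)``.
    """

    segment: str
    origin: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.R = np.asarray(self.R, float).reshape(3, 3)
        if np.abs(self.R @ self.R.T - np.eye(3)).max() > 1e-10:
            raise ValueError(f"frame {self.segment}: R not orthonormal")
        if abs(np.linalg.det(self.R) - 1.0) > 1e-10:
            raise ValueError(f"frame {self.segment}: det(R) != +1")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        out = (pts - self.origin) @ self.R.T
        return out[0] if np.asarray(points).ndim == 1 else out

    def to_global(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        out = pts @ self.R + self.origin
        return out[0] if np.asarray(points).ndim == 1 else out


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"degenerate (zero-length) axis while building {what}")
    return v / n


def _frame_from_axes(segment: str, origin, primary: np.ndarray, primary_name: str,
                     secondary: np.ndarray, secondary_name: str) -> SegmentFrame:
    """Build a proper rotation keeping ``primary`` exact; axes named 'x','y','z'."""
    p = _unit(primary, f"{segment} frame")
    s = secondary - np.dot(secondary, p) * p
    n = np.linalg.norm(s)
    if n < 1e-9:
        raise ValueError(
            f"{segment} frame: defining points are collinear "
            f"({secondary_name} parallel to {primary_name})")
    s = s / n
    axes = {primary_name: p, secondary_name: s}
    missing = [a for a in ("x", "y", "z") if a not in axes][0]
    # complete the right-handed triad: x = y cross z, y = z cross x, z = x cross y
    if missing == "x":
        axes["x"] = np.cross(axes["y"], axes["z"])
    elif missing == "y":
        axes["y"] = np.cross(axes["z"], axes["x"])
    else:
        axes["z"] = np.cross(axes["x"], axes["y"])
    R = np.vstack([axes["x"], axes["y"], axes["z"]])
    return SegmentFrame(segment, np.asarray(origin, float), R)


def _pelvis_frame(ls: LandmarkSet) -> SegmentFrame:
    asis_r, asis_l = ls.get("ASIS_r"), ls.get("ASIS_l")
    psis_r, psis_l = ls.get("PSIS_r"), ls.get("PSIS_l")
    asis_mid = 0.5 * (asis_r + asis_l)
    psis_mid = 0.5 * (psis_r + psis_l)
    z = asis_r - asis_l
    if np.linalg.norm(z) < 1e-9:
        raise ValueError("pelvis frame: ASIS_r coincides with ASIS_l (collinear definition)")
    x = asis_mid - psis_mid
    return _frame_from_axes("pelvis", asis_mid, z, "z", x, "x")


def _femur_frame(ls: LandmarkSet, side: str) -> SegmentFrame:
    hip = ls.get(f"femoral_head_center_{side}")
    med = ls.get(f"femoral_epicondyle_med_{side}")
    lat = ls.get(f"femoral_epicondyle_lat_{side}")
    knee = 0.5 * (med + lat)
    y = hip - knee
    z = lat - med if side == "r" else med - lat   # z toward the body's right on both sides
    return _frame_from_axes(f"femur_{side}", hip, y, "y", z, "z")


def _tibia_frame(ls: LandmarkSet, side: str) -> SegmentFrame:
    cm = ls.get(f"tibial_condyle_med_{side}")
    cl = ls.get(f"tibial_condyle_lat_{side}")
    mm = ls.get(f"malleolus_med_{side}")
    ml = ls.get(f"malleolus_lat_{side}")
    knee = 0.5 * (cm + cl)
    ankle = 0.5 * (mm + ml)
    y = knee - ankle
    z = cl - cm if side == "r" else cm - cl
    return _frame_from_axes(f"tibia_{side}", knee, y, "y", z, "z")


def _patella_frame(ls: LandmarkSet, side: str) -> SegmentFrame:
    apex = ls.get(f"patella_apex_{side}")
    base = ls.get(f"patella_base_{side}")
    med = ls.get(f"patella_med_{side}")
    lat = ls.get(f"patella_lat_{side}")
    y = base - apex
    z = lat - med if side == "r" else med - lat
    return _frame_from_axes(f"patella_{side}", apex, y, "y", z, "z")


def build_frames(landmarks: LandmarkSet, segments: list[str] | None = None) -> dict[str, SegmentFrame]:
    """Construct ISB segment frames from a (warped) landmark set in meters.

    Returns a map segment -> :class:`SegmentFrame` for every segment whose
    required landmarks are present (or for ``segments`` if given, raising on
    any missing landmark).
    """
    ls = landmarks.to_m()
    builders = {"pelvis": lambda: _pelvis_frame(ls)}
    for side in ("r", "l"):
        builders[f"femur_{side}"] = (lambda s=side: _femur_frame(ls, s))
        builders[f"tibia_{side}"] = (lambda s=side: _tibia_frame(ls, s))
        builders[f"patella_{side}"] = (lambda s=side: _patella_frame(ls, s))

    wanted = segments if segments is not None else list(builders)
    frames: dict[str, SegmentFrame] = {}
    for seg in wanted:
        if seg.startswith("foot_"):
            continue  # handled below from the tibia
        if seg not in builders:
            raise ValueError(f"no frame recipe for segment {seg!r}")
        try:
            frames[seg] = builders[seg]()
        except KeyError as e:
            if segments is None:
                continue
            raise ValueError(f"segment {seg}: missing required landmark {e.args[0]}") from e

    # foot frames: tibia rotation translated to the ankle center
    for side in ("r", "l"):
        seg = f"foot_{side}"
        if segments is not None and seg not in segments:
            continue
        try:
            mm = ls.get(f"malleolus_med_{side}")
            ml = ls.get(f"malleolus_lat_{side}")
        except KeyError:
            if segments is None:
                continue
            raise
        tib = frames.get(f"tibia_{side}")
        if tib is not None:
            frames[seg] = SegmentFrame(seg, 0.5 * (mm + ml), tib.R.copy())
    return frames


def localize(model: ModelGeometry, frames: dict[str, SegmentFrame]) -> ModelGeometry:
    """Express every model point in its segment's frame.

    Joint centers are expressed twice: in the parent frame
    (``center_in_parent``) and the child frame (``center_in_child``).  The
    frames used are stored in the model metadata so that
    :func:`globalize` can reconstruct global coordinates exactly.
    """
    if model.coordinates != "global":
        raise ValueError("localize expects a model in global coordinates")
    used = {p.segment for mu in model.muscles for p in mu.points}
    used |= {w.segment for w in model.wrap_surfaces}
    used |= {j.parent_segment for j in model.joints} | {j.child_segment for j in model.joints}
    missing = sorted(s for s in used if s not in frames)
    if missing:
        raise ValueError(f"no frame for segment(s): {missing}")

    out = model.copy()
    for mu in out.muscles:
        for p in mu.points:
            p.position = frames[p.segment].to_local(p.position)
    for j in out.joints:
        j.center_in_parent = frames[j.parent_segment].to_local(j.center_global)
        j.center_in_child = frames[j.child_segment].to_local(j.center_global)
    for w in out.wrap_surfaces:
        f = frames[w.segment]
        w.axis_point = f.to_local(w.axis_point)
        w.axis_dir = f.R @ w.axis_dir
    out.coordinates = "local"
    out.metadata["frames"] = {
        seg: {"origin": f.origin.tolist(), "R": f.R.tolist()} for seg, f in frames.items()
    }
    return out


def frames_from_model(model: ModelGeometry) -> dict[str, SegmentFrame]:
    """Recover the SegmentFrames stored in a localized model's metadata."""
    raw = model.metadata.get("frames")
    if raw is None:
        raise ValueError("model metadata carries no frames")
    return {seg: SegmentFrame(seg, np.asarray(d["origin"]), np.asarray(d["R"]))
            for seg, d in raw.items()}


def globalize(model: ModelGeometry, frames: dict[str, SegmentFrame] | None = None) -> ModelGeometry:
    """Inverse of :func:`localize`: reconstruct global coordinates."""
    if model.coordinates != "local":
        raise ValueError("globalize expects a localized model")
    frames = frames or frames_from_model(model)
    out = model.copy()
    for mu in out.muscles:
        for p in mu.points:
            p.position = frames[p.segment].to_global(p.position)
    for j in out.joints:
        j.center_global = frames[j.parent_segment].to_global(j.center_in_parent)
    for w in out.wrap_surfaces:
        f = frames[w.segment]
        w.axis_point = f.to_global(w.axis_point)
        w.axis_dir = f.R.T @ w.axis_dir
    out.coordinates = "global"
    return out
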