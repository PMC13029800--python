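"""Musculotendon path length, cylinder wrapping, moment arms and via-point
optimization.

Path length is the sum of straight segments, except where a wrap cylinder is
assigned to a segment and the straight line penetrates it; then the segment
is replaced by the shortest tangent-arc-tangent path over the cylinder
(single-obstacle method).  On the cylinder the geodesic is a helix, so the
3D wrapped length is ``sqrt(L2d^2 + dz^2)`` with ``L2d`` the tangent-arc-
tangent length in the cylinder's cross-sectional plane and ``dz`` the axial
travel.

The moment arm of a muscle about a hinge coordinate is the tendon-excursion
derivative ``r(theta) = -dL/dtheta``, evaluated by central differences
(default step 0.5 degrees, one-sided at the grid ends).

The via-point optimizer minimizes the waveform-matching objective

    total = dmean + dmax + dshape + dshift + pdrop

against reference (generic-model) moment-arm waveforms, moving each movable
via point within a per-point search radius (hard ball constraint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import ModelGeometry, MusclePathDef, WrapCylinder

DEFAULT_DTHETA = np.deg2rad(0.5)


# ---------------------------------------------------------------------------
# Pose kinematics
# ---------------------------------------------------------------------------

@dataclass
class _Rigid:
    R: np.ndarray
    t: np.ndarray

    @classmethod
    def identity(cls) -> "_Rigid":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "_Rigid") -> "_Rigid":
        return _Rigid(self.R @ other.R, self.R @ other.t + self.t)

    def apply(self, p: np.ndarray) -> np.ndarray:
        return self.R @ p + self.t

    def apply_vec(self, v: np.ndarray) -> np.ndarray:
        return self.R @ v


def _axis_angle(axis: np.ndarray, theta: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _rotation_about(center: np.ndarray, axis: np.ndarray, theta: float) -> _Rigid:
    R = _axis_angle(axis, theta)
    return _Rigid(R, center - R @ center)


def segment_transforms(model: ModelGeometry, joint_pose: dict[str, float]) -> dict[str, _Rigid]:
    """Rigid transform (neutral global -> posed global) for every segment.

    ``joint_pose`` maps joint name to angle (rad); unspecified joints sit at
    zero.  Segments are chained from the (fixed) root via the model's joints;
    welded segments ride with their weld parent.
    """
    if model.coordinates != "global":
        raise ValueError("segment kinematics require a model in global coordinates")
    parents: dict[str, tuple[str, object]] = {}
    for j in model.joints:
        parents[j.child_segment] = (j.parent_segment, j)
    for child, parent in model.welds:
        parents[child] = (parent, None)

    transforms: dict[str, _Rigid] = {}

    def resolve(seg: str) -> _Rigid:
        if seg in transforms:
            return transforms[seg]
        if seg not in parents:
            transforms[seg] = _Rigid.identity()   # root (pelvis)
            return transforms[seg]
        parent, joint = parents[seg]
        T_parent = resolve(parent)
        if joint is None:
            T = T_parent
        else:
            theta = float(joint_pose.get(joint.name, 0.0))
            lo, hi = joint.range
            if theta < lo - 1e-9 or theta > hi + 1e-9:
                raise ValueError(
                    f"joint {joint.name}: angle {theta:.4f} outside range [{lo:.4f}, {hi:.4f}]")
            T = T_parent.compose(_rotation_about(joint.center_global, joint.axis, theta))
        transforms[seg] = T
        return T

    for seg in model.segments:
        resolve(seg)
    return transforms


# ---------------------------------------------------------------------------
# Cylinder wrapping
# ---------------------------------------------------------------------------

class EndpointInsideCylinderError(ValueError):
    """A path endpoint lies inside its wrap cylinder: geometrically impossible."""


def _cylinder_frame(axis_point: np.ndarray, axis_dir: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis (rows) with the cylinder axis as the third row."""
    w = axis_dir / np.linalg.norm(axis_dir)
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, w)) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(a, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.vstack([u, v, w]), axis_point


_QUADRANT_DIRS = {"+x": np.array([1.0, 0.0]), "-x": np.array([-1.0, 0.0]),
                  "+y": np.array([0.0, 1.0]), "-y": np.array([0.0, -1.0])}


def _wrap_segment_2d(P: np.ndarray, Q: np.ndarray, R: float, side: float):
    """Tangent-arc-tangent path around the circle of radius R for one side.

    Returns (length_2d, arc_angle, tangent_pts) or None if that side's
    solution is not a valid wrap.
    """
    dp, dq = np.linalg.norm(P), np.linalg.norm(Q)
    phi_p = np.arccos(np.clip(R / dp, -1, 1))
    phi_q = np.arccos(np.clip(R / dq, -1, 1))
    ap, aq = np.arctan2(P[1], P[0]), np.arctan2(Q[1], Q[0])
    # tangent points on the chosen side (arc midpoint toward +side normal)
    tp = ap - side * phi_p
    tq = aq + side * phi_q
    Tp = R * np.array([np.cos(tp), np.sin(tp)])
    Tq = R * np.array([np.cos(tq), np.sin(tq)])
    # arc from tp to tq traveling in -side direction (around the obstacle)
    arc = (side * (tp - tq)) % (2 * np.pi)
    lt = np.sqrt(max(dp * dp - R * R, 0.0)) + np.sqrt(max(dq * dq - R * R, 0.0))
    return lt + R * arc, arc, (Tp, Tq, tp, tq)


def _segment_penetrates_2d(P: np.ndarray, Q: np.ndarray, R: float) -> bool:
    d = Q - P
    dd = float(d @ d)
    if dd == 0.0:
        return bool(np.linalg.norm(P) < R)
    t = float(np.clip(-(P @ d) / dd, 0.0, 1.0))
    closest = P + t * d
    return bool(np.linalg.norm(closest) < R)


def wrapped_segment_length(p: np.ndarray, q: np.ndarray, cyl_axis_point: np.ndarray,
                           cyl_axis_dir: np.ndarray, radius: float,
                           active_quadrant: str = "+x") -> float:
    """Length of the muscle segment p->q deflected by the cylinder.

    Straight distance if the segment clears the cylinder; otherwise the
    tangent-arc-tangent geodesic length, with the wrap side chosen by
    ``active_quadrant`` (the arc is placed on the side of the cylinder whose
    local direction it names).  Raises
    :class:`EndpointInsideCylinderError` when an endpoint is inside.
    """
    B, origin = _cylinder_frame(cyl_axis_point, cyl_axis_dir)
    pl = B @ (np.asarray(p, float) - origin)
    ql = B @ (np.asarray(q, float) - origin)
    P, Q = pl[:2], ql[:2]
    for name, X in (("p", P), ("q", Q)):
        if np.linalg.norm(X) < radius - 1e-12:
            raise EndpointInsideCylinderError(
                f"path endpoint {name} lies inside wrap cylinder "
                f"(axis distance {np.linalg.norm(X):.6f} < radius {radius:.6f})")
    if not _segment_penetrates_2d(P, Q, radius):
        return float(np.linalg.norm(np.asarray(q, float) - np.asarray(p, float)))

    sols = {}
    for side in (+1.0, -1.0):
        L2d, arc, (Tp, Tq, tp, tq) = _wrap_segment_2d(P, Q, radius, side)
        mid_angle = tp - side * arc / 2.0
        mid_dir = np.array([np.cos(mid_angle), np.sin(mid_angle)])
        sols[side] = (L2d, arc, mid_dir)
    qdir = _QUADRANT_DIRS.get(active_quadrant)
    if qdir is None:
        raise ValueError(f"unknown active_quadrant {active_quadrant!r}")
    # prefer the side whose arc midpoint points into the active quadrant;
    # among admissible sides take the shorter path
    scored = sorted(sols.items(), key=lambda kv: (-np.sign(kv[1][2] @ qdir), kv[1][0]))
    side, (L2d, arc, _mid) = scored[0]
    dz = ql[2] - pl[2]
    return float(np.sqrt(L2d * L2d + dz * dz))


def path_length(model: ModelGeometry, muscle: str, joint_pose: dict[str, float] | None = None) -> float:
    """Musculotendon length (m) of ``muscle`` at the given joint pose."""
    joint_pose = joint_pose or {}
    mu = model.muscle(muscle)
    T = segment_transforms(model, joint_pose)
    pts = [T[p.segment].apply(p.position) for p in mu.points]
    wrap_of_segment = {}
    for wname, i in mu.wraps:
        wrap_of_segment[int(i)] = model.wrap(wname)

    total = 0.0
    for i in range(len(pts) - 1):
        w = wrap_of_segment.get(i)
        if w is None:
            total += float(np.linalg.norm(pts[i + 1] - pts[i]))
        else:
            Tw = T[w.segment]
            axis_point = Tw.apply(w.axis_point)
            axis_dir = Tw.apply_vec(w.axis_dir)
            total += wrapped_segment_length(pts[i], pts[i + 1], axis_point, axis_dir,
                                            w.radius, w.active_quadrant)
    return total


# ---------------------------------------------------------------------------
# Moment arms
# ---------------------------------------------------------------------------

@dataclass
class MomentArmWaveform:
    """Moment arm (m) of one muscle about one hinge joint over an angle grid."""

    muscle: str
    joint: str
    angles: np.ndarray   # rad, strictly increasing
    values: np.ndarray   # m

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, float)
        self.values = np.asarray(self.values, float)
        if self.angles.shape != self.values.shape:
            raise ValueError("angle grid and values differ in length")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angle grid must be strictly increasing")
        if not (np.all(np.isfinite(self.angles)) and np.all(np.isfinite(self.values))):
            raise ValueError("waveform must be finite")


def moment_arm(model: ModelGeometry, muscle: str, joint: str,
               angle_grid: np.ndarray, dtheta: float = DEFAULT_DTHETA,
               base_pose: dict[str, float] | None = None) -> MomentArmWaveform:
    """Tendon-excursion moment arm r(theta) = -dL/dtheta on ``angle_grid``.

    Central differences with step ``dtheta``; one-sided at the joint-range
    ends.  ``base_pose`` fixes the other joints' angles (default zero).
    """
    j = model.joint(joint)
    grid = np.asarray(angle_grid, float)
    lo, hi = j.range
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise ValueError(f"angle grid [{grid.min():.4f}, {grid.max():.4f}] outside "
                         f"joint range [{lo:.4f}, {hi:.4f}]")
    base = dict(base_pose or {})

    def L(theta: float) -> float:
        pose = dict(base)
        pose[joint] = theta
        return path_length(model, muscle, pose)

    vals = np.empty_like(grid)
    for i, th in enumerate(grid):
        a, b = th - dtheta, th + dtheta
        if a < lo:
            vals[i] = -(L(th + dtheta) - L(th)) / dtheta
        elif b > hi:
            vals[i] = -(L(th) - L(th - dtheta)) / dtheta
        else:
            vals[i] = -(L(b) - L(a)) / (2 * dtheta)
    return MomentArmWaveform(muscle, joint, grid, vals)


def joint_grid(j, n: int = 61) -> np.ndarray:
    return np.linspace(j.range[0], j.range[1], n)


# ---------------------------------------------------------------------------
# Wrap-surface checks
# ---------------------------------------------------------------------------

def _axis_distance(point: np.ndarray, w: WrapCylinder) -> float:
    d = point - w.axis_point
    d_perp = d - np.dot(d, w.axis_dir) * w.axis_dir
    return float(np.linalg.norm(d_perp))


def _neighbouring_points(mu: MusclePathDef, seg_index: int):
    return mu.points[seg_index], mu.points[seg_index + 1]


def check_wrap_violations(model: ModelGeometry) -> list[tuple[str, str, str, float]]:
    """List (muscle, point label, cylinder, axis distance) for every path
    point neighbouring a wrap whose distance to the cylinder axis is below
    the radius.  Evaluated in the neutral pose, global coordinates."""
    if model.coordinates != "global":
        raise ValueError("check_wrap_violations expects global coordinates")
    out = []
    for mu in model.muscles:
        for wname, i in mu.wraps:
            w = model.wrap(wname)
            for p in _neighbouring_points(mu, i):
                dist = _axis_distance(p.position, w)
                if dist < w.radius:
                    out.append((mu.name, p.label, wname, dist))
    return out


def reduce_wrap_radii(model: ModelGeometry, safety: float = 0.98) -> ModelGeometry:
    """Shrink violating wrap-cylinder radii below the nearest via point.

    For each cylinder with at least one neighbouring path point closer to
    its axis than its radius, the radius becomes ``safety`` times the
    minimum axis distance over all its neighbouring points.  Non-violating
    cylinders are untouched; the result has zero violations and the
    operation is idempotent.
    """
    violations = check_wrap_violations(model)
    if not violations:
        return model
    out = model.copy()
    min_dist: dict[str, float] = {}
    for mu in out.muscles:
        for wname, i in mu.wraps:
            w = out.wrap(wname)
            for p in _neighbouring_points(mu, i):
                d = _axis_distance(p.position, w)
                min_dist[wname] = min(min_dist.get(wname, np.inf), d)
    changed = {}
    for _, _, wname, _ in violations:
        w = out.wrap(wname)
        new_r = safety * min_dist[wname]
        if new_r < w.radius:
            changed[wname] = {"old_radius": w.radius, "new_radius": new_r}
            w.radius = new_r
    if changed:
        out.metadata.setdefault("wrap_radius_reductions", {}).update(changed)
    return out


# ---------------------------------------------------------------------------
# Optimization objective
# ---------------------------------------------------------------------------

@dataclass
class ObjectiveConfig:
    pdrop_weight: float = 1.0     # meters-equivalent per counted drop interval
    pdrop_tau: float = 0.15       # drop fraction of max |moment arm| that counts
    dshift_weight: float = 0.1    # objective per meter of via-point displacement


@dataclass
class ObjectiveBreakdown:
    dmean: float
    dmax: float
    dshape: float
    dshift: float
    pdrop: float

    @property
    def total(self) -> float:
        return self.dmean + self.dmax + self.dshape + self.dshift + self.pdrop


def count_sudden_drops(values: np.ndarray, tau: float) -> int:
    """Number of adjacent-sample intervals where the moment arm magnitude
    drops by more than ``tau`` times the waveform's max magnitude."""
    v = np.abs(np.asarray(values, float))
    scale = v.max()
    if scale <= 0:
        return 0
    drops = v[:-1] - v[1:]
    return int(np.sum(drops > tau * scale))


def objective(ref: MomentArmWaveform, cand: MomentArmWaveform,
              via_displacement: float = 0.0,
              cfg: ObjectiveConfig | None = None) -> ObjectiveBreakdown:
    """Waveform-matching objective: dmean + dmax + dshape + dshift + pdrop.

    dmean / dmax are the mean / maximum absolute moment-arm differences;
    dshape compares the end-to-end height of the two waveforms; dshift
    penalizes the Euclidean displacement of the moved via point from its
    warped initial position; pdrop counts sudden adjacent-sample drops in
    the candidate (wrap-induced collapses).
    """
    cfg = cfg or ObjectiveConfig()
    if ref.angles.shape != cand.angles.shape or not np.allclose(ref.angles, cand.angles):
        raise ValueError("waveform angle grids differ")
    diff = np.abs(cand.values - ref.values)
    dmean = float(diff.mean())
    dmax = float(diff.max())
    dshape = float(abs((cand.values[-1] - cand.values[0]) - (ref.values[-1] - ref.values[0])))
    dshift = cfg.dshift_weight * float(via_displacement)
    pdrop = cfg.pdrop_weight * count_sudden_drops(cand.values, cfg.pdrop_tau)
    return ObjectiveBreakdown(dmean, dmax, dshape, dshift, pdrop)


# ---------------------------------------------------------------------------
# Via-point optimization
# ---------------------------------------------------------------------------

def _muscle_joints(model: ModelGeometry, mu: MusclePathDef) -> list[str]:
    """Joints whose angle changes the muscle's length (spanned joints)."""
    spanned = []
    for j in model.joints:
        grid = np.array([j.range[0], 0.5 * (j.range[0] + j.range[1]), j.range[1]])
        try:
            wf = moment_arm(model, mu.name, j.name, grid)
        except ValueError:
            continue
        if np.max(np.abs(wf.values)) > 1e-6:
            spanned.append(j.name)
    return spanned


def optimize_via_points(
    model: ModelGeometry,
    muscle: str,
    ref_waveforms: dict[str, MomentArmWaveform],
    seed: int = 0,
    cfg: ObjectiveConfig | None = None,
    maxiter: int = 120,
) -> tuple[ModelGeometry, dict[str, ObjectiveBreakdown]]:
    """Adjust a muscle's movable via points to match reference moment arms.

    ``ref_waveforms`` maps joint name -> reference waveform (on a grid inside
    the model's joint range).  Points named in the muscle's
    ``search_radius_of`` are optimized sequentially (distal to proximal),
    each within a hard ball of its search radius around its initial (warped)
    position, using a seeded derivative-free Nelder-Mead restarted from the
    initial point; candidate displacements are projected onto the ball before
    evaluation so the constraint can never be violated.

    Returns the optimized model and ``{"before": ..., "after": ...}``
    objective breakdowns summed over the reference joints.
    """
    cfg = cfg or ObjectiveConfig()
    out = model.copy()
    mu = out.muscle(muscle)
    movable = [p for p in mu.points if p.label in mu.search_radius_of]
    for lbl, r in mu.search_radius_of.items():
        if not r > 0:
            raise ValueError(f"muscle {muscle}: infeasible search radius {r} for {lbl!r}")

    def eval_objective(displacement_total: float) -> ObjectiveBreakdown:
        parts = []
        for jname, ref in ref_waveforms.items():
            cand = moment_arm(out, muscle, jname, ref.angles)
            parts.append(objective(ref, cand, 0.0, cfg))
        agg = ObjectiveBreakdown(
            dmean=sum(p.dmean for p in parts),
            dmax=sum(p.dmax for p in parts),
            dshape=sum(p.dshape for p in parts),
            dshift=cfg.dshift_weight * displacement_total,
            pdrop=sum(p.pdrop for p in parts),
        )
        return agg

    initial_positions = {p.label: p.position.copy() for p in movable}
    before = eval_objective(0.0)

    rng = np.random.default_rng(seed)
    # distal -> proximal: path points are ordered origin (proximal) first
    for p in sorted(movable, key=lambda p: -mu.points.index(p)):
        radius = mu.search_radius_of[p.label]
        x0_global = initial_positions[p.label]

        def project(d: np.ndarray) -> np.ndarray:
            n = np.linalg.norm(d)
            return d if n <= radius else d * (radius / n)

        def f(d: np.ndarray) -> float:
            d = project(d)
            p.position = x0_global + d
            total_disp = sum(np.linalg.norm(q.position - initial_positions[q.label])
                             for q in movable)
            try:
                val = eval_objective(total_disp).total
            except EndpointInsideCylinderError:
                val = 1e6
            return val

        best_d = np.zeros(3)
        best_f = f(best_d)
        # deterministic multi-start: origin plus a few seeded points in the ball
        starts = [np.zeros(3)] + [project(rng.normal(scale=radius / 2, size=3))
                                  for _ in range(2)]
        for s0 in starts:
            res = minimize(f, s0, method="Nelder-Mead",
                           options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-9,
                                    "initial_simplex": _simplex_around(s0, radius / 8)})
            d = project(res.x)
            val = f(d)
            if val < best_f - 1e-15:
                best_f, best_d = val, d
        p.position = x0_global + project(best_d)

    after = eval_objective(sum(np.linalg.norm(q.position - initial_positions[q.label])
                               for q in movable))
    if after.total > before.total:
        # never accept a worse model than the input
        for p in movable:
            p.position = initial_positions[p.label]
        after = before
    out.metadata.setdefault("via_point_optimization", {})[muscle] = {
        "before_total": before.total, "after_total": after.total,
        "moved": {p.label: float(np.linalg.norm(p.position - initial_positions[p.label]))
                  for p in movable},
    }
    return out, {"before": before, "after": after}


def _simplex_around(x0: np.ndarray, step: float) -> np.ndarray:
    n = len(x0)
    simplex = np.tile(x0, (n + 1, 1))
    for i in range(n):
        simplex[i + 1, i] += step
    return simplex
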