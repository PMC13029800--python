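"""Penalized 3D thin-plate spline warping.

The personalization step maps the template's muscle path points, joint
centers, wrap-surface positions and skin markers into a participant's
anatomy using a thin-plate spline (TPS) fitted to homologous bone-landmark
pairs.  The 3D TPS with kernel ``U(r) = r`` (the biharmonic fundamental
solution up to a constant) interpolates exactly at zero penalty and
reproduces any affine map with zero bending energy.

The smoothing fit solves the regularized square system

    [K - lam*I   P] [W]   [T]
    [P^T         0] [A] = [0]

where ``K_ij = U(|s_i - s_j|)``, ``P = [1 | S]`` (N x 4), ``W`` the kernel
weights and ``A`` the affine part; lambda is interpreted in the units of the
solve (meters here).  Two penalty levels are used downstream: 0.001 for
bone/muscle points and 0.02 for the display surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LandmarkSet, ModelGeometry

#: default bending penalties: points (bone landmarks, muscle paths, markers)
#: and display surfaces.
LAMBDA_POINTS = 0.001
LAMBDA_SURFACE = 0.02


@dataclass
class TpsConfig:
    lambda_points: float = LAMBDA_POINTS
    lambda_surface: float = LAMBDA_SURFACE

    def __post_init__(self) -> None:
        if self.lambda_points < 0 or self.lambda_surface < 0:
            raise ValueError("TPS penalties must be >= 0")


@dataclass
class TpsTransform:
    """A fitted 3D thin-plate spline: affine part plus kernel weights."""

    source_landmarks: np.ndarray   # (N, 3)
    affine: np.ndarray             # (3, 4): f_aff(x) = affine @ [x; 1]
    kernel_weights: np.ndarray     # (N, 3)
    lam: float
    bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_tps(self, points)


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


def fit_tps(source: np.ndarray, target: np.ndarray, lam: float = 0.0) -> TpsTransform:
    """Fit a 3D TPS mapping homologous ``source`` -> ``target`` point pairs.

    Parameters
    ----------
    source, target:
        ``(N, 3)`` arrays of paired points, same order; N >= 5 and the source
        must not be coplanar (the affine part would be rank-deficient).
    lam:
        Bending penalty >= 0.  At 0 the map interpolates the targets exactly;
        larger values trade landmark residual for smoothness.
    """
    source = np.asarray(source, float)
    target = np.asarray(target, float)
    if source.ndim != 2 or source.shape[1] != 3:
        raise ValueError(f"source must be (N, 3), got {source.shape}")
    if source.shape != target.shape:
        raise ValueError(f"source {source.shape} and target {target.shape} differ")
    n = source.shape[0]
    if n < 5:
        raise ValueError(f"need >= 5 landmark pairs, got {n}")
    if lam < 0:
        raise ValueError("lambda must be >= 0")

    P = np.hstack([np.ones((n, 1)), source])           # (N, 4)
    # degenerate (coplanar/collinear) source detection via the polynomial block
    sv = np.linalg.svd(source - source.mean(axis=0), compute_uv=False)
    if sv[-1] <= 1e-10 * sv[0]:
        raise ValueError(
            "degenerate source configuration: landmarks are coplanar/collinear "
            f"(relative rank defect, singular values {sv})")

    K = _kernel_matrix(source, source)
    A = np.zeros((n + 4, n + 4))
    # with the conditionally negative definite kernel U(r)=r the penalized
    # normal equations read (K - lam*I) W + P A = T; equivalently one may
    # flip the kernel sign and add the ridge.  This sign gives the classical
    # smoothing behavior: residual non-decreasing, energy non-increasing in
    # lam.  lam is NOT rescaled by the landmark count: at the published
    # penalty levels an N-proportional ridge over-smooths a 110-landmark
    # solve in meters enough to bias recovered joint centers by ~1 mm.
    A[:n, :n] = K - lam * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = target

    sol = np.linalg.solve(A, rhs)
    W = sol[:n]                                        # (N, 3)
    # sol[n:] rows are the [constant; x; y; z] polynomial coefficients
    affine = np.hstack([sol[n + 1:].T, sol[n:n + 1].T])  # (3, 4) = [M | b]

    # U(r) = r is conditionally negative definite, so on the side-condition
    # subspace trace(W^T K W) <= 0; the bending energy is its negation.
    bending = max(-float(np.einsum("id,ij,jd->", W, K, W)), 0.0)
    return TpsTransform(source.copy(), affine, W, float(lam), bending)


def apply_tps(t: TpsTransform, points: np.ndarray) -> np.ndarray:
    """Evaluate the fitted spline at ``points`` (``(M, 3)`` or ``(3,)``)."""
    pts = np.asarray(points, float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    U = _kernel_matrix(pts, t.source_landmarks)        # (M, N)
    out = pts @ t.affine[:, :3].T + t.affine[:, 3] + U @ t.kernel_weights
    return out[0] if single else out


def residual_rms(t: TpsTransform, target: np.ndarray) -> float:
    """RMS landmark residual of the fit at its own source points."""
    pred = apply_tps(t, t.source_landmarks)
    return float(np.sqrt(np.mean(np.sum((pred - np.asarray(target, float)) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Model warping
# ---------------------------------------------------------------------------

def fit_pair_transforms(
    template_landmarks: LandmarkSet,
    participant_landmarks: LandmarkSet,
    cfg: TpsConfig | None = None,
) -> tuple[TpsTransform, TpsTransform]:
    """Fit the points-level and surface-level TPS from homologous landmark sets.

    Both sets must carry identical names in identical order, in ISB meters.
    Returns ``(points_tps, surface_tps)`` fitted at ``lambda_points`` and
    ``lambda_surface`` respectively from the same pairs.
    """
    cfg = cfg or TpsConfig()
    if template_landmarks.names != participant_landmarks.names:
        missing = sorted(set(template_landmarks.names) ^ set(participant_landmarks.names))
        raise ValueError(
            "template/participant landmark sets are not homologous; "
            f"non-shared or re-ordered names: {missing or 'same names, different order'}")
    src = template_landmarks.to_m().coords
    dst = participant_landmarks.to_m().coords
    return (fit_tps(src, dst, cfg.lambda_points),
            fit_tps(src, dst, cfg.lambda_surface))


def warp_geometry(
    model: ModelGeometry,
    template_landmarks: LandmarkSet,
    participant_landmarks: LandmarkSet,
    cfg: TpsConfig | None = None,
) -> ModelGeometry:
    """Warp a model's geometry onto a participant's landmark constellation.

    A single TPS is fitted from ALL homologous bone-landmark pairs at the
    points penalty and applied to muscle path points, skin markers, joint
    centers, the model's own landmark copy, and wrap-cylinder axis points.
    Wrap radii, lengths and orientations are preserved (only the surface
    translation follows the warp).  The model must be in global coordinates.
    """
    if model.coordinates != "global":
        raise ValueError("warp_geometry requires a model in global coordinates")
    points_tps, _surface_tps = fit_pair_transforms(template_landmarks, participant_landmarks, cfg)

    warped = model.copy()
    for mu in warped.muscles:
        for p in mu.points:
            p.position = apply_tps(points_tps, p.position)
    warped.skin_markers = warped.skin_markers.with_coords(
        apply_tps(points_tps, warped.skin_markers.to_m().coords))
    warped.skin_markers.units = "m"
    for j in warped.joints:
        j.center_global = apply_tps(points_tps, j.center_global)
        j.center_in_parent = None
        j.center_in_child = None
    for w in warped.wrap_surfaces:
        w.axis_point = apply_tps(points_tps, w.axis_point)
        # radius, length, axis_dir preserved from the generic-scaled model
    if warped.landmarks is not None:
        warped.landmarks = warped.landmarks.with_coords(
            apply_tps(points_tps, warped.landmarks.to_m().coords))
        warped.landmarks.units = "m"
    warped.metadata.setdefault("warp", {}).update({
        "lambda_points": points_tps.lam,
        "bending_energy_points": points_tps.bending_energy,
        "n_landmark_pairs": int(points_tps.source_landmarks.shape[0]),
    })
    return warped


def warp_mesh(mesh, template_landmarks: LandmarkSet, participant_landmarks: LandmarkSet,
              cfg: TpsConfig | None = None):
    """Warp a display surface mesh with the surface-level (smoother) TPS."""
    _points_tps, surface_tps = fit_pair_transforms(template_landmarks, participant_landmarks, cfg)
    out = mesh.copy()
    out.vertices = apply_tps(surface_tps, np.asarray(mesh.vertices, float))
    return out


def apply_manual_corrections(model: ModelGeometry, corrections: dict) -> ModelGeometry:
    """Replace individually named muscle path points with corrected positions.

    ``corrections`` maps ``"muscle_name/point_label"`` to a 3-vector (meters,
    model frame).  All other points are untouched; the correction log is
    retained in the model metadata.
    """
    out = model.copy()
    log = []
    for key, pos in corrections.items():
        try:
            muscle_name, label = key.split("/", 1)
        except ValueError:
            raise KeyError(f"correction key {key!r} must be 'muscle/point_label'") from None
        mu = out.muscle(muscle_name)       # raises KeyError for absent muscle
        p = mu.point(label)                # raises KeyError for absent point
        old = p.position.copy()
        p.position = np.asarray(pos, float).reshape(3)
        log.append({"point": key, "from": old.tolist(), "to": p.position.tolist()})
    if log:
        out.metadata.setdefault("manual_corrections", []).extend(log)
    return out
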