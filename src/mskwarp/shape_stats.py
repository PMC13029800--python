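"""Generalized Procrustes superimposition, shape PCA, waveform peaks and
correlation.

Shape variation across models is summarized by superimposing each model's
combined point cloud (bone landmarks plus muscle path points, concatenated in
a fixed order), removing translation, rotation and size, and running a PCA on
the aligned, flattened coordinates.  "Standardized" means centroid-size
normalization within the superimposition (classical geometric-morphometrics
practice), not per-coordinate z-scoring.  Reflections are not allowed: all
Procrustes rotations are proper (det = +1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

def _center_and_size(x: np.ndarray) -> tuple[np.ndarray, float]:
    c = x - x.mean(axis=0)
    size = float(np.linalg.norm(c))
    return c, size


def _procrustes_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||a @ R - b||_F (no reflection)."""
    U, _s, Vt = np.linalg.svd(a.T @ b)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def gpa_superimpose(shapes: list[np.ndarray], tol: float = 1e-10,
                    max_iter: int = 200) -> tuple[list[np.ndarray], np.ndarray]:
    """Iterative GPA: center, scale to unit centroid size, rotate to the mean.

    Returns (aligned shapes, mean shape).  Aligned shapes have centroid 0 and
    centroid size 1; the mean is the fixed point of the alignment (itself
    re-normalized each iteration).  Converges when the mean moves less than
    ``tol`` in Frobenius norm.
    """
    if len(shapes) < 2:
        raise ValueError("need >= 2 shapes")
    k = shapes[0].shape
    arrs = []
    for i, s in enumerate(shapes):
        s = np.asarray(s, float)
        if s.shape != k:
            raise ValueError(f"shape {i} has {s.shape}, expected {k}")
        c, size = _center_and_size(s)
        if size <= 0:
            raise ValueError(f"shape {i} is degenerate (all points coincident)")
        arrs.append(c / size)

    mean = arrs[0].copy()
    for _ in range(max_iter):
        aligned = [a @ _procrustes_rotation(a, mean) for a in arrs]
        new_mean = np.mean(aligned, axis=0)
        c, size = _center_and_size(new_mean)
        new_mean = c / size
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            arrs = aligned
            break
        mean = new_mean
        arrs = aligned
    # final re-normalization of each aligned shape (rotation preserves size)
    aligned = []
    for a in arrs:
        c, size = _center_and_size(a)
        aligned.append(c / size)
    return aligned, mean


# ---------------------------------------------------------------------------
# Shape PCA
# ---------------------------------------------------------------------------

@dataclass
class ShapePcaResult:
    mean_shape: np.ndarray        # (K, 3)
    loadings: np.ndarray          # (n_components, 3K), orthonormal rows
    scores: np.ndarray            # (n_models, n_components)
    variance_fraction: np.ndarray  # per component, sums to 1 over all
    model_labels: list[str]

    def n_components(self) -> int:
        return self.loadings.shape[0]


def pca_shapes(aligned: list[np.ndarray], model_labels: list[str] | None = None) -> ShapePcaResult:
    """PCA of flattened aligned shapes about their mean.

    Variance fractions come from the squared singular values; scores and
    loadings reconstruct the inputs exactly over all components:
    ``mean + scores @ loadings`` = aligned shapes (flattened).
    """
    if len(aligned) < 2:
        raise ValueError("need >= 2 shapes for PCA")
    X = np.stack([np.asarray(a, float).ravel() for a in aligned])   # (n, 3K)
    labels = model_labels or [f"model_{i}" for i in range(len(aligned))]
    if len(labels) != X.shape[0]:
        raise ValueError("model_labels length mismatch")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # drop numerically-null directions beyond the data rank
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    scores = U * s
    var = s ** 2
    frac = var / var.sum() if var.sum() > 0 else var
    K = aligned[0].shape[0]
    return ShapePcaResult(mean.reshape(K, 3), Vt, scores, frac, list(labels))


def reconstruct_along_pc(res: ShapePcaResult, component: int, score: float) -> np.ndarray:
    """Shape at ``score`` standard-coordinate units along one PC (K, 3)."""
    if not 0 <= component < res.n_components():
        raise IndexError(f"component {component} not retained (have {res.n_components()})")
    flat = res.mean_shape.ravel() + score * res.loadings[component]
    return flat.reshape(res.mean_shape.shape)


def reconstruct_from_scores(res: ShapePcaResult, scores: np.ndarray) -> np.ndarray:
    flat = res.mean_shape.ravel() + np.asarray(scores, float) @ res.loadings
    return flat.reshape(res.mean_shape.shape)


# ---------------------------------------------------------------------------
# Waveform peaks and correlation
# ---------------------------------------------------------------------------

@dataclass
class PeakReport:
    peak1_value: float
    peak1_time_pct: float
    peak2_value: float
    peak2_time_pct: float


def waveform_peaks(values: np.ndarray, times_pct: np.ndarray | None = None,
                   split_pct: float = 50.0) -> PeakReport:
    """First (early-stance) and second (late-stance) peaks of a waveform.

    The waveform is sampled on 0-100% stance (uniform grid assumed when
    ``times_pct`` is omitted).  Peak 1 is the maximum over [0, split)%,
    peak 2 the maximum over [split, 100]%.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("empty waveform")
    t = (np.linspace(0.0, 100.0, v.size) if times_pct is None
         else np.asarray(times_pct, float))
    if t.shape != v.shape:
        raise ValueError("times and values differ in length")
    early = t < split_pct
    late = ~early
    if not early.any() or not late.any():
        raise ValueError("waveform does not cover both sides of the split")
    i1 = int(np.flatnonzero(early)[np.argmax(v[early])])
    i2 = int(np.flatnonzero(late)[np.argmax(v[late])])
    return PeakReport(float(v[i1]), float(t[i1]), float(v[i2]), float(t[i2]))


def pearson_r(x: np.ndarray, y: np.ndarray,
              exclude: int | None = None,
              labels: list[str] | None = None,
              exclude_label: str | None = None) -> float:
    """Pearson correlation; optional leave-one-out by index or label."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D vectors")
    if exclude_label is not None:
        if labels is None:
            raise ValueError("exclude_label requires labels")
        exclude = labels.index(exclude_label)
    if exclude is not None:
        keep = np.ones(len(x), bool)
        keep[exclude] = False
        x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
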