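"""Generalized Procrustes analysis and tangent-space shape variables.

Superimposition removes translation (centering), size (scaling every
configuration to unit centroid size) and orientation (optimal proper
rotation to the iteratively re-estimated mean). Shape statistics are then
computed on the principal components of the tangent-space residuals: the
aligned coordinates minus the mean, orthogonally projected onto the plane
tangent to the unit-size sphere at the mean. For k 2D landmarks this
leaves exactly 2k - 4 dimensions with non-zero variance (2 for
translation, 1 for scale and 1 for rotation are consumed by the
superimposition), e.g. an 8-dimensional shape space for 6 landmarks.

Whether the linear tangent approximation is adequate is an empirical
question answered by :func:`distortion_check`, which compares tangent
(Euclidean) and Procrustes distances; for cranial data with realistic
shape scatter their matrix correlation should exceed 0.99.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import LandmarkDataset

logger = logging.getLogger("allotraj")

GPA_TOL = 1e-10
GPA_MAX_ITER = 100
EIGENVALUE_RTOL = 1e-10


def centroid_size(coords: np.ndarray) -> float:
    """Square root of summed squared landmark distances from their centroid (mm)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 3:
        raise ValueError("need a (k, d) configuration with k >= 3")
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs <= 1e-12:
        raise ValueError("degenerate configuration: all landmarks coincident")
    return cs


def midplane_project(coords: np.ndarray) -> np.ndarray:
    """Project nominally coplanar 3D landmarks onto their least-squares plane.

    The plane passes through the centroid; the returned 2D coordinates are
    expressed in an orthonormal in-plane basis, so within-plane geometry
    (all inter-landmark distances) is preserved for exactly coplanar input.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("midplane_project expects a (k, 3) configuration")
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-9 * s[0]:
        raise ValueError("collinear landmarks: best-fitting plane is undefined")
    basis = vt[:2]
    # deterministic orientation: largest-|component| of each axis positive
    for i in range(2):
        j = int(np.argmax(np.abs(basis[i])))
        if basis[i, j] < 0:
            basis[i] = -basis[i]
    return centered @ basis.T


def _rotation_to(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimizing ||source @ R - target||."""
    u, _, vt = np.linalg.svd(source.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] = -u[:, -1]
        r = u @ vt
    return r


@dataclass
class AlignedShapes:
    """Superimposed configurations with their original sizes.

    ``aligned`` holds unit-centroid-size, centered, rotated configurations
    (n, k, d); ``centroid_sizes`` / ``ln_cs`` record size before scaling.
    """

    aligned: np.ndarray
    centroid_sizes: np.ndarray
    ln_cs: np.ndarray
    mean_shape: np.ndarray
    iterations: int
    converged: bool

    @property
    def n(self) -> int:
        return self.aligned.shape[0]


def gpa_align(dataset: LandmarkDataset | np.ndarray,
              tol: float = GPA_TOL, max_iter: int = GPA_MAX_ITER) -> AlignedShapes:
    """Iterative full generalized Procrustes alignment.

    Each configuration is centered, scaled to unit centroid size and
    rotated (proper rotations only; reflections would be anatomically
    meaningless) to the current mean; the mean is recomputed, re-scaled to
    unit centroid size, and iteration continues until its change falls
    below ``tol``. A final rotation pass against the converged mean leaves
    every configuration optimally rotated to the reported mean shape.
    """
    coords = dataset.coords_array() if isinstance(dataset, LandmarkDataset) else np.asarray(dataset, float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 specimens")
    cs = np.array([centroid_size(c) for c in coords])
    x = coords - coords.mean(axis=1, keepdims=True)
    x = x / cs[:, None, None]
    mean = x[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        rotated = np.stack([c @ _rotation_to(c, mean) for c in x])
        new_mean = rotated.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        new_mean /= np.sqrt((new_mean**2).sum())
        delta = float(np.sqrt(((new_mean - mean) ** 2).sum()))
        x, mean = rotated, new_mean
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (last mean change {delta:.3e})"
        )
    x = np.stack([c @ _rotation_to(c, mean) for c in x])
    logger.info("GPA converged in %d iterations (n=%d)", iterations, n)
    return AlignedShapes(
        aligned=x, centroid_sizes=cs, ln_cs=np.log(cs),
        mean_shape=mean, iterations=iterations, converged=True,
    )


@dataclass
class TangentScores:
    """PC scores of tangent-space residuals and the orthonormal basis behind them.

    ``scores`` is (n, m) with m the number of non-zero-eigenvalue
    components (2k - 4 for generic 2D data); ``basis`` rows are
    orthonormal loading vectors in flattened (k*d) coordinate space;
    ``center`` is the flattened coordinate mean. Landmark shapes are
    reconstructed as ``center + scores @ basis``.
    """

    scores: np.ndarray
    eigenvalues: np.ndarray
    basis: np.ndarray
    center: np.ndarray
    k: int
    d: int

    @property
    def m(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        """Map score vectors back to (k, d) landmark configurations."""
        scores = np.atleast_2d(np.asarray(scores, float))
        flat = self.center + scores @ self.basis
        out = flat.reshape(len(scores), self.k, self.d)
        return out[0] if out.shape[0] == 1 else out

    def tangent_residuals(self) -> np.ndarray:
        """Projected residuals in flattened coordinates, (n, k*d)."""
        return self.scores @ self.basis


def tangent_pc_scores(aligned: AlignedShapes) -> TangentScores:
    """Principal components of tangent-projected aligned coordinates.

    Residuals about the coordinate mean are orthogonally projected onto
    the tangent plane at the (unit-size) Procrustes mean before the PCA,
    which removes the residual radial direction exactly; components with
    eigenvalue > 1e-10 x largest are retained. Sign convention: each
    component's largest-magnitude loading is positive.
    """
    n, k, d = aligned.aligned.shape
    if n < 2:
        raise ValueError("need at least 2 specimens")
    flat = aligned.aligned.reshape(n, k * d)
    center = flat.mean(axis=0)
    resid = flat - center
    mvec = aligned.mean_shape.reshape(-1)
    mvec = mvec / np.linalg.norm(mvec)
    resid = resid - np.outer(resid @ mvec, mvec)
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > EIGENVALUE_RTOL * eig[0]
    basis = vt[keep]
    for i in range(basis.shape[0]):
        j = int(np.argmax(np.abs(basis[i])))
        if basis[i, j] < 0:
            basis[i] = -basis[i]
    scores = resid @ basis.T
    return TangentScores(
        scores=scores, eigenvalues=eig[keep], basis=basis, center=center, k=k, d=d
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes chord distance between two configurations.

    Both are centered and scaled to unit centroid size; b is optimally
    rotated onto a (proper rotation); the root summed squared coordinate
    difference is returned.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    ac = ac / centroid_size(a)
    bc = bc / centroid_size(b)
    bc = bc @ _rotation_to(bc, ac)
    return float(np.sqrt(((ac - bc) ** 2).sum()))


def distortion_check(aligned: AlignedShapes, scores: TangentScores):
    """Tangent-space vs Procrustes distance diagnostic.

    Returns ``(r, table)``: the Pearson matrix correlation between all
    pairwise tangent (Euclidean, on the PC scores) and Procrustes
    distances, plus the paired distance table for plotting. Values of r
    above 0.99 indicate negligible tangent-projection distortion.
    """
    n = aligned.n
    if n < 3:
        raise ValueError("distortion check needs at least 3 specimens (>= 3 pairs)")
    from scipy.spatial.distance import pdist

    tangent = pdist(scores.scores)
    proc = np.array([
        procrustes_distance(aligned.aligned[i], aligned.aligned[j])
        for i, j in itertools.combinations(range(n), 2)
    ])
    if tangent.std() == 0 or proc.std() == 0:
        raise ValueError("zero variance in a distance set: correlation undefined")
    r = float(np.corrcoef(tangent, proc)[0, 1])
    pairs = [f"{i}-{j}" for i, j in itertools.combinations(range(n), 2)]
    table = pd.DataFrame(
        {"pair": pairs, "tangent_distance": tangent, "procrustes_distance": proc}
    )
    return r, table
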