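"""Metric MDS embedding of a session's paths and convex-hull exploration area.

Each of a participant's paths becomes one point in a 2-D plane such that
inter-point distances approximate the pairwise path dissimilarities
(metric multidimensional scaling, minimizing the normalized metric stress

    stress = sum_{i<j} (d_ij - delta_ij)^2 / sum_{i<j} d_ij^2

with delta the embedded Euclidean distances).  The optimizer is iterative
stress majorization (SMACOF/Guttman transform) initialized from classical
scaling plus seeded random restarts; raw stress is non-increasing across
majorization steps by construction, and the per-iteration history is kept.

How widely a participant explored the space of possible paths is then
quantified as the area of the convex hull of their embedded points.  Hull
area is invariant under the rotation/reflection/translation indeterminacy
of MDS, so the arbitrary orientation of the embedding cannot affect it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .similarity import DistanceMatrix

__all__ = [
    "Embedding2D",
    "ExplorationArea",
    "classical_scaling",
    "mds_embed",
    "convex_hull_area",
]

logger = logging.getLogger(__name__)

MAX_ITER_DEFAULT = 512
TOL_DEFAULT = 1e-8


@dataclass(frozen=True)
class Embedding2D:
    points: np.ndarray  # (n, n_dims)
    stress: float  # normalized metric stress of the kept solution
    n_iter: int
    seed: int
    stress_history: np.ndarray  # per-iteration normalized stress (kept restart)
    path_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class ExplorationArea:
    area: float
    hull_vertices: tuple[int, ...]


def _as_matrix(d: DistanceMatrix | np.ndarray) -> np.ndarray:
    D = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.any(np.isnan(D)):
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(D, D.T, rtol=1e-8, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    return D


def classical_scaling(D: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Torgerson classical scaling: eigendecomposition of the
    double-centered squared-distance matrix.  Exact when D is Euclidean
    and embeddable in n_dims."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _pairwise(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=-1))


def _normalized_stress(D: np.ndarray, delta: np.ndarray, denom: float) -> float:
    iu = np.triu_indices_from(D, k=1)
    return float(np.sum((D[iu] - delta[iu]) ** 2) / denom)


def _smacof_single(
    D: np.ndarray, X0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, np.ndarray]:
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    denom = float(np.sum(D[iu] ** 2))
    if denom == 0.0:  # all-zero distances: any coincident layout is exact
        return np.zeros_like(X0), 0.0, np.array([0.0])
    X = X0.copy()
    delta = _pairwise(X)
    history = [_normalized_stress(D, delta, denom)]
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(delta > 0, D / np.where(delta > 0, delta, 1.0), 0.0)
        B = -ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n  # Guttman transform (unit weights)
        delta = _pairwise(X)
        history.append(_normalized_stress(D, delta, denom))
        if history[-2] - history[-1] < tol:
            break
    return X, history[-1], np.asarray(history)


def mds_embed(
    d: DistanceMatrix | np.ndarray,
    n_dims: int = 2,
    seed: int = 0,
    n_restarts: int = 4,
    max_iter: int = MAX_ITER_DEFAULT,
    tol: float = TOL_DEFAULT,
) -> Embedding2D:
    """Embed a dissimilarity matrix in n_dims by metric stress majorization.

    One restart starts from classical scaling, the rest from seeded random
    configurations; the lowest-stress solution is kept.  Deterministic
    given (matrix, seed).
    """
    D = _as_matrix(d)
    n = D.shape[0]
    if n < 2:
        raise ValueError("MDS requires at least 2 objects")
    rng = np.random.default_rng(seed)
    scale = np.max(D) or 1.0
    inits = [classical_scaling(D, n_dims)]
    for _ in range(max(0, n_restarts - 1)):
        inits.append(rng.normal(scale=scale, size=(n, n_dims)))
    best: tuple[np.ndarray, float, np.ndarray] | None = None
    for X0 in inits:
        X, stress, history = _smacof_single(D, X0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, history)
    X, stress, history = best
    path_ids = d.path_ids if isinstance(d, DistanceMatrix) else ()
    return Embedding2D(
        points=X,
        stress=stress,
        n_iter=len(history) - 1,
        seed=seed,
        stress_history=history,
        path_ids=tuple(path_ids),
    )


def convex_hull_area(emb: Embedding2D | np.ndarray) -> ExplorationArea:
    """Area of the convex hull of the embedded points.

    Returns area 0 (with a logged note) for fewer than 3 distinct points
    or collinear configurations, where exploration area is undefined but
    still reportable.
    """
    pts = emb.points if isinstance(emb, Embedding2D) else np.asarray(emb, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("hull area requires (n, 2) points")
    distinct = np.unique(pts, axis=0)
    if distinct.shape[0] < 3:
        logger.warning("convex hull undefined for < 3 distinct points; area = 0")
        return ExplorationArea(area=0.0, hull_vertices=())
    try:
        hull = ConvexHull(pts)
    except QhullError:
        logger.warning("degenerate (collinear) point set; hull area = 0")
        return ExplorationArea(area=0.0, hull_vertices=())
    # in 2-D, ConvexHull.volume is the enclosed area
    return ExplorationArea(area=float(hull.volume), hull_vertices=tuple(hull.vertices))
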