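"""Feature vectors, mirror-min distances and nearest-neighbour uniqueness.

Each resampled path is summarized by a 480-value feature vector

    v = [hx(200), hy(200), h'x(20), h'y(20), h''x(20), h''y(20)]

where h is the path at 200 arc-length-uniform points, h' and h'' are
first/second differences along the resampled index, and the derivative
components are averaged over 20 consecutive bins of 10 points.  Including
derivatives gives extra weight to changes of direction (corners vs smooth
curves).

The distance between two paths is the p-norm (default 2) of the feature
difference, minimized over the left-right mirror image of one path, so a
path and its reflection about the vertical task axis count as the same
option.  Mirror-min distances need not satisfy the triangle inequality.

The uniqueness of a path is its distance to the nearest neighbour in a
pooled corpus (all participants, all sessions): large uniqueness means no
other drawn path resembles it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model import GeometryError, TaskGeometry
from .preprocess import ResampledPath

__all__ = [
    "PathFeatures",
    "DistanceMatrix",
    "feature_length",
    "build_features",
    "mirror_path",
    "path_distance",
    "distance_matrix",
    "uniqueness_scores",
    "uniqueness_from_matrix",
]

BIN_SIZE_DEFAULT = 10


@dataclass(frozen=True)
class PathFeatures:
    """Feature vector of a path and of its mirror image (same layout)."""

    v: np.ndarray
    mirror_v: np.ndarray
    path_id: str
    participant_id: str | None = None
    n_resample: int = 200
    bin_size: int = BIN_SIZE_DEFAULT


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise mirror-min distances over a path set.

    Symmetric with zero diagonal; the triangle inequality is *not*
    guaranteed (taking the minimum over mirrors can violate it).
    """

    values: np.ndarray  # (n, n)
    p_norm: float
    path_ids: tuple[str, ...]
    participant_ids: tuple[str | None, ...] = ()

    @property
    def n(self) -> int:
        return self.values.shape[0]


def feature_length(n_resample: int = 200, bin_size: int = BIN_SIZE_DEFAULT) -> int:
    """Length of the feature vector: 2*n_resample + 4*(n_resample/bin_size)."""
    return 2 * n_resample + 4 * (n_resample // bin_size)


def _feature_vector(
    coords: np.ndarray, bin_size: int, derivative_weight: float
) -> np.ndarray:
    n = coords.shape[0]
    if n % bin_size != 0:
        raise ValueError(
            f"bin_size {bin_size} must divide the number of resampled points {n}"
        )
    # first/second differences along the arc index, zero-padded at the
    # front so each component keeps n values and bins evenly
    d1 = np.vstack([np.zeros(2), np.diff(coords, axis=0)])
    d2 = np.vstack([np.zeros(2), np.diff(d1, axis=0)])
    n_bins = n // bin_size
    d1b = d1.reshape(n_bins, bin_size, 2).mean(axis=1)
    d2b = d2.reshape(n_bins, bin_size, 2).mean(axis=1)
    return np.concatenate(
        [
            coords[:, 0],
            coords[:, 1],
            derivative_weight * d1b[:, 0],
            derivative_weight * d1b[:, 1],
            derivative_weight * d2b[:, 0],
            derivative_weight * d2b[:, 1],
        ]
    )


def mirror_path(path: ResampledPath, geom: TaskGeometry) -> ResampledPath:
    """Reflect a path about the vertical line through the circle centers."""
    if not geom.is_vertical:
        raise GeometryError(
            "mirroring requires vertically aligned start/end centers"
        )
    axis = geom.axis_x
    coords = path.coords.copy()
    coords[:, 0] = 2.0 * axis - coords[:, 0]
    return ResampledPath(
        coords=coords,
        total_length=path.total_length,
        path_id=path.path_id,
        participant_id=path.participant_id,
    )


def build_features(
    path: ResampledPath,
    geom: TaskGeometry,
    bin_size: int = BIN_SIZE_DEFAULT,
    derivative_weight: float = 1.0,
) -> PathFeatures:
    """Assemble the feature vector and its mirror-image counterpart."""
    v = _feature_vector(path.coords, bin_size, derivative_weight)
    mirrored = mirror_path(path, geom)
    mv = _feature_vector(mirrored.coords, bin_size, derivative_weight)
    return PathFeatures(
        v=v,
        mirror_v=mv,
        path_id=path.path_id,
        participant_id=path.participant_id,
        n_resample=path.n_points,
        bin_size=bin_size,
    )


def _minkowski(diff: np.ndarray, p: float) -> float:
    return float(np.sum(np.abs(diff) ** p) ** (1.0 / p))


def _pointwise_sum(diff: np.ndarray, n: int, n_bins: int) -> float:
    """Alternative metric: sum over corresponding points (and derivative
    bins) of the per-point Euclidean distance, instead of one norm over the
    concatenated vector."""
    blocks = np.split(diff, np.cumsum([n, n, n_bins, n_bins, n_bins]))
    total = float(np.hypot(blocks[0], blocks[1]).sum())
    total += float(np.hypot(blocks[2], blocks[3]).sum())
    total += float(np.hypot(blocks[4], blocks[5]).sum())
    return total


def path_distance(
    a: PathFeatures,
    b: PathFeatures,
    p_norm: float = 2,
    variant: str = "norm",
) -> float:
    """Mirror-min feature distance between two paths.

    ``variant="norm"`` (default) takes the p-norm of the concatenated
    feature difference; ``variant="pointwise_sum"`` sums the per-point
    Euclidean distances between corresponding points/bins.
    """
    if a.v.shape != b.v.shape:
        raise ValueError(
            f"feature length mismatch: {a.v.shape[0]} vs {b.v.shape[0]}"
        )
    if variant == "norm":
        return min(
            _minkowski(a.v - b.v, p_norm), _minkowski(a.v - b.mirror_v, p_norm)
        )
    if variant == "pointwise_sum":
        n = a.n_resample
        n_bins = n // a.bin_size
        return min(
            _pointwise_sum(a.v - b.v, n, n_bins),
            _pointwise_sum(a.v - b.mirror_v, n, n_bins),
        )
    raise ValueError(f"unknown distance variant {variant!r}")


def _stacked(features) -> tuple[np.ndarray, np.ndarray]:
    V = np.stack([f.v for f in features])
    M = np.stack([f.mirror_v for f in features])
    return V, M


def distance_matrix(features, p_norm: float = 2) -> DistanceMatrix:
    """All pairwise mirror-min distances (vectorized)."""
    features = list(features)
    if len(features) < 2:
        raise ValueError("distance matrix requires at least 2 paths")
    lengths = {f.v.shape[0] for f in features}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent feature lengths: {sorted(lengths)}")
    V, M = _stacked(features)
    plain = cdist(V, V, "minkowski", p=p_norm)
    crossed = cdist(V, M, "minkowski", p=p_norm)
    # ||v_i - Mv_j|| = ||Mv_i - v_j|| because mirroring is a per-coordinate
    # isometry; enforce exact symmetry numerically
    crossed = np.minimum(crossed, crossed.T)
    values = np.minimum(plain, crossed)
    values = np.minimum(values, values.T)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(
        values=values,
        p_norm=p_norm,
        path_ids=tuple(f.path_id for f in features),
        participant_ids=tuple(f.participant_id for f in features),
    )


def uniqueness_from_matrix(dm: DistanceMatrix) -> pd.DataFrame:
    """Per-path uniqueness u_i = min_{j != i} d_ij with the achieved
    nearest neighbour recorded for audit."""
    values = dm.values.copy()
    np.fill_diagonal(values, np.inf)
    nn = values.argmin(axis=1)
    ui = values[np.arange(dm.n), nn]
    return pd.DataFrame(
        {
            "path_id": list(dm.path_ids),
            "participant_id": list(dm.participant_ids)
            if dm.participant_ids
            else [None] * dm.n,
            "uniqueness": ui,
            "nearest_neighbour_id": [dm.path_ids[j] for j in nn],
            "p_norm": dm.p_norm,
        }
    )


def uniqueness_scores(corpus, p_norm: float = 2) -> pd.DataFrame:
    """Uniqueness of every path against the whole pooled corpus."""
    corpus = list(corpus)
    if len(corpus) < 2:
        raise ValueError("uniqueness requires a corpus of at least 2 paths")
    return uniqueness_from_matrix(distance_matrix(corpus, p_norm=p_norm))
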