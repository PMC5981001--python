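"""Path validation, tremor smoothing and arc-length-uniform resampling.

Raw drawn paths are irregular in time and space.  Downstream comparison
requires each path to be expressed as a fixed number of points uniformly
spaced along the curve (arc-length parameterization), which discards the
drawing speed while preserving the order in which places are visited.
An optional centered moving average over a 250 ms window removes ~4 Hz
tremor oscillations before resampling.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import RawTrajectory, TaskGeometry, ValidationError

__all__ = [
    "DegeneratePathError",
    "PathValidity",
    "ArcLengthProfile",
    "ResampledPath",
    "validate_path",
    "smooth_trajectory",
    "arc_length_profile",
    "resample",
    "resample_polyline",
]

N_RESAMPLE_DEFAULT = 200
SMOOTH_WINDOW_DEFAULT = 0.25  # seconds


class DegeneratePathError(ValidationError):
    """Path has zero length (all samples coincide) and cannot be resampled."""


@dataclass(frozen=True)
class PathValidity:
    valid: bool
    reason: str | None = None  # "start" or "end" when invalid


@dataclass(frozen=True)
class ArcLengthProfile:
    """Cumulative distance s along the path at each retained source sample."""

    s: np.ndarray  # (m,), non-decreasing, s[0] == 0
    xy: np.ndarray  # (m, 2) source positions with consecutive duplicates removed

    @property
    def total_length(self) -> float:
        return float(self.s[-1])


@dataclass(frozen=True)
class ResampledPath:
    """A path re-expressed as n points uniform in arc length."""

    coords: np.ndarray  # (n, 2)
    total_length: float
    path_id: str
    participant_id: str | None = None

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]


def validate_path(traj: RawTrajectory, geom: TaskGeometry) -> PathValidity:
    """Check the endpoint rule: a path counts as valid iff it starts within
    ``endpoint_tolerance`` of the start center and ends within the same
    tolerance of the end center (boundary inclusive)."""
    start = np.asarray(geom.start_center, dtype=float)
    end = np.asarray(geom.end_center, dtype=float)
    d_start = float(np.linalg.norm(traj.xy[0] - start))
    d_end = float(np.linalg.norm(traj.xy[-1] - end))
    if d_start > geom.endpoint_tolerance:
        return PathValidity(False, "start")
    if d_end > geom.endpoint_tolerance:
        return PathValidity(False, "end")
    return PathValidity(True, None)


def smooth_trajectory(
    traj: RawTrajectory, window: float = SMOOTH_WINDOW_DEFAULT
) -> RawTrajectory:
    """Centered moving average over a time window (default 250 ms).

    Each coordinate is replaced by the mean of all samples whose timestamp
    lies within +-window/2 of its own; near the path ends the window is
    truncated.  Timestamps are unchanged.  A 250 ms boxcar nulls a 4 Hz
    oscillation (one full period per window), which is what makes it a
    tremor control.
    """
    if window <= 0:
        raise ValueError("smoothing window must be positive")
    t = traj.t
    xy = traj.xy
    n = len(t)
    half = window / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    csum = np.vstack([np.zeros(2), np.cumsum(xy, axis=0)])
    counts = (hi - lo).astype(float)
    means = (csum[hi] - csum[lo]) / counts[:, None]
    samples = np.column_stack([t, means])
    return RawTrajectory(path_id=traj.path_id, samples=samples, onset=traj.onset)


def _dedup(xy: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicate positions (touchscreens emit repeats)."""
    if len(xy) < 2:
        return xy
    keep = np.ones(len(xy), dtype=bool)
    keep[1:] = np.any(np.diff(xy, axis=0) != 0.0, axis=1)
    return xy[keep]


def arc_length_profile(traj: RawTrajectory | np.ndarray) -> ArcLengthProfile:
    """Cumulative Euclidean distance along the sampled polyline."""
    xy = traj.xy if isinstance(traj, RawTrajectory) else np.asarray(traj, dtype=float)
    xy = _dedup(xy)
    if len(xy) < 2:
        raise DegeneratePathError("path has zero total length")
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise DegeneratePathError("path has zero total length")
    return ArcLengthProfile(s=s, xy=xy)


def resample_polyline(xy: np.ndarray, n_resample: int) -> tuple[np.ndarray, float]:
    """Resample a polyline at n points uniform in arc length.

    Returns (coords, total_length).  Coordinates are linear interpolations
    between source vertices at arc lengths k*L/(n-1); the first and last
    output points are the exact source endpoints.
    """
    if n_resample < 2:
        raise ValueError("n_resample must be >= 2")
    profile = arc_length_profile(xy)
    length = profile.total_length
    targets = np.linspace(0.0, length, n_resample)
    coords = np.column_stack(
        [
            np.interp(targets, profile.s, profile.xy[:, 0]),
            np.interp(targets, profile.s, profile.xy[:, 1]),
        ]
    )
    coords[0] = profile.xy[0]
    coords[-1] = profile.xy[-1]
    return coords, length


def resample(
    traj: RawTrajectory,
    n_resample: int = N_RESAMPLE_DEFAULT,
    participant_id: str | None = None,
) -> ResampledPath:
    """Arc-length-uniform resampling of a raw trajectory.

    Depends only on the sample positions, never on timestamps: the same
    geometric path drawn faster or slower resamples identically.
    """
    coords, length = resample_polyline(traj.xy, n_resample)
    return ResampledPath(
        coords=coords,
        total_length=length,
        path_id=traj.path_id,
        participant_id=participant_id,
    )
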