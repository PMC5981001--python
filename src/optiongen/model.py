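"""Domain model for the two-point path-drawing (option-generation) task.

The task: a participant repeatedly draws paths on a touchscreen from a
start circle to an end circle placed 204 mm above it, within a fixed time
budget.  These types carry the task geometry, the raw timestamped
trajectories, the session structure (participant x session x condition),
and whole cohorts.

All geometry is in millimetres; origin at the screen bottom-left with y
increasing upward, so the end circle has the larger y.  Timestamps are
seconds relative to session start.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TaskGeometry",
    "RawTrajectory",
    "Session",
    "Cohort",
    "ValidationError",
    "GeometryError",
    "TASK_KINDS",
]

TASK_KINDS = (
    "option_generation",
    "motor_execution",
    "cued_action",
    "option_selection",
)


class ValidationError(ValueError):
    """A domain invariant is violated by the data."""


class GeometryError(ValidationError):
    """Task geometry is invalid or unsupported for the requested operation."""


@dataclass(frozen=True)
class TaskGeometry:
    """Placement of the start/end circles, validity margin and time budget.

    Defaults are the option-generation task layout: two circles of radius
    13 mm, vertically aligned 204 mm apart, a 21 mm endpoint tolerance for
    counting a path as valid, and a 240 s budget.
    """

    start_center: tuple[float, float] = (0.0, 0.0)
    end_center: tuple[float, float] = (0.0, 204.0)
    circle_radius: float = 13.0
    endpoint_tolerance: float = 21.0
    time_limit: float = 240.0
    screen_width: float = 509.0
    screen_height: float = 286.0

    def __post_init__(self) -> None:
        if self.endpoint_tolerance < self.circle_radius:
            raise GeometryError(
                "endpoint_tolerance must be >= circle_radius "
                f"({self.endpoint_tolerance} < {self.circle_radius})"
            )
        if self.chord_length <= 0:
            raise GeometryError("start and end centers must be distinct")
        if self.time_limit <= 0:
            raise GeometryError("time_limit must be positive")

    @property
    def chord_length(self) -> float:
        """Straight-line distance between the two circle centers (mm)."""
        dx = self.end_center[0] - self.start_center[0]
        dy = self.end_center[1] - self.start_center[1]
        return math.hypot(dx, dy)

    @property
    def is_vertical(self) -> bool:
        return math.isclose(
            self.start_center[0], self.end_center[0], abs_tol=1e-9
        )

    @property
    def axis_x(self) -> float:
        """x-coordinate of the vertical task axis (the mirror line).

        Only defined when the circle centers are vertically aligned.
        """
        if not self.is_vertical:
            raise GeometryError(
                "mirror axis undefined: circle centers are not vertically aligned"
            )
        return float(self.start_center[0])

    def with_time_limit(self, seconds: float) -> "TaskGeometry":
        return replace(self, time_limit=seconds)


@dataclass
class RawTrajectory:
    """One drawn path: ordered (t, x, y) samples, t in s, x/y in mm.

    ``samples`` is an (n, 3) float array.  ``onset`` is the path's start
    time relative to session start; sample timestamps are absolute within
    the session (first sample's t equals ``onset`` for recorded data).
    """

    path_id: str
    samples: np.ndarray
    onset: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValidationError(
                f"path {self.path_id!r}: samples must be an (n, 3) array of (t, x, y)"
            )
        if arr.shape[0] < 2:
            raise ValidationError(
                f"path {self.path_id!r}: at least 2 samples required, got {arr.shape[0]}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"path {self.path_id!r}: non-finite sample values")
        if np.any(np.diff(arr[:, 0]) < 0):
            raise ValidationError(
                f"path {self.path_id!r}: timestamps must be non-decreasing"
            )
        seg = np.linalg.norm(np.diff(arr[:, 1:3], axis=0), axis=1)
        if seg.sum() <= 0:
            raise ValidationError(
                f"path {self.path_id!r}: zero total length after duplicate removal"
            )
        self.samples = arr

    @property
    def t(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def xy(self) -> np.ndarray:
        return self.samples[:, 1:3]

    @property
    def duration(self) -> float:
        """Drawing time of this path: t_last - t_first (s)."""
        return float(self.samples[-1, 0] - self.samples[0, 0])


@dataclass
class Session:
    """All trajectories of one participant in one session of one task."""

    participant_id: str
    session_index: int
    condition: str
    task_kind: str
    trajectories: list[RawTrajectory] = field(default_factory=list)
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task_kind not in TASK_KINDS:
            raise ValidationError(
                f"unknown task_kind {self.task_kind!r}; expected one of {TASK_KINDS}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.participant_id, int(self.session_index), self.task_kind)

    def validate(self, geometry: TaskGeometry) -> None:
        seen: set[str] = set()
        for traj in self.trajectories:
            if traj.path_id in seen:
                raise ValidationError(
                    f"session {self.key}: duplicate path_id {traj.path_id!r}"
                )
            seen.add(traj.path_id)
            if not (0.0 <= traj.onset <= geometry.time_limit):
                raise ValidationError(
                    f"session {self.key}: path {traj.path_id!r} onset "
                    f"{traj.onset:.3f}s outside [0, {geometry.time_limit}]"
                )


@dataclass
class Cohort:
    """A set of sessions sharing one task geometry."""

    sessions: list[Session]
    geometry: TaskGeometry = field(default_factory=TaskGeometry)
    provenance: str = ""

    def validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for sess in self.sessions:
            if sess.key in seen:
                raise ValidationError(f"duplicate session key {sess.key}")
            seen.add(sess.key)
            # cued/selection tasks run on a 90 s budget; motor execution is
            # untimed (ten lines); option generation on the cohort budget
            geom = self.geometry
            if sess.task_kind in ("cued_action", "option_selection"):
                geom = geom.with_time_limit(max(geom.time_limit, 90.0))
            elif sess.task_kind == "motor_execution":
                geom = geom.with_time_limit(math.inf)
            sess.validate(geom)

    def iter_sessions(self, task_kind: str | None = None):
        for sess in self.sessions:
            if task_kind is None or sess.task_kind == task_kind:
                yield sess

    @property
    def n_paths(self) -> int:
        return sum(len(s.trajectories) for s in self.sessions)
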