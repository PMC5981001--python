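"""Flat-file readers/writers for trajectory cohorts.

One sample per row, CSV with a fixed column order, so any tool can consume
the data.  Floats are written with 10 significant digits ("%.10g"), which
is the documented round-trip precision.  Screen coordinates recorded in
device pixels (columns ``x_px``/``y_px``) are converted to mm on ingestion
using the ``pixels_per_mm_x``/``pixels_per_mm_y`` calibration from the
geometry config.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .model import Cohort, RawTrajectory, Session, TaskGeometry, ValidationError

__all__ = [
    "TRAJECTORY_COLUMNS",
    "FormatError",
    "read_cohort",
    "write_cohort",
    "load_geometry",
    "write_geometry",
    "read_covariates",
    "write_covariates",
]

TRAJECTORY_COLUMNS = [
    "participant_id",
    "session_index",
    "condition",
    "task_kind",
    "path_id",
    "sample_index",
    "t_s",
    "x_mm",
    "y_mm",
]
COVARIATE_COLUMNS = ["participant_id", "session_index", "covariate_name", "value"]
FLOAT_FORMAT = "%.10g"

_GEOMETRY_FIELDS = (
    "start_center",
    "end_center",
    "circle_radius",
    "endpoint_tolerance",
    "time_limit",
    "screen_width",
    "screen_height",
)


class FormatError(ValueError):
    """The file does not conform to the documented tabular format."""


def load_geometry(path: str | Path) -> tuple[TaskGeometry, dict]:
    """Load a TaskGeometry plus calibration from a YAML or JSON config.

    Returns ``(geometry, calibration)`` where calibration holds
    ``pixels_per_mm_x``/``pixels_per_mm_y`` (default 1.0 each).
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: geometry config must be a mapping")
    kwargs = {}
    for name in _GEOMETRY_FIELDS:
        if name in data:
            val = data[name]
            kwargs[name] = tuple(val) if name.endswith("_center") else float(val)
    calibration = {
        "pixels_per_mm_x": float(data.get("pixels_per_mm_x", 1.0)),
        "pixels_per_mm_y": float(data.get("pixels_per_mm_y", 1.0)),
    }
    return TaskGeometry(**kwargs), calibration


def write_geometry(geometry: TaskGeometry, path: str | Path) -> Path:
    path = Path(path)
    data = asdict(geometry)
    data["start_center"] = list(geometry.start_center)
    data["end_center"] = list(geometry.end_center)
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


def write_cohort(
    cohort: Cohort,
    path: str | Path,
    covariates_path: str | Path | None = None,
) -> Path:
    """Write a cohort as the flat per-sample CSV (deterministic byte output).

    Sessions are ordered by (participant_id, session_index, task_kind),
    paths by first appearance, samples by index.  A covariate long table is
    written alongside when ``covariates_path`` is given.
    """
    cohort.validate()
    path = Path(path)
    rows: list[tuple] = []
    for sess in sorted(cohort.sessions, key=lambda s: s.key):
        for traj in sess.trajectories:
            for k, (t, x, y) in enumerate(traj.samples):
                rows.append(
                    (
                        sess.participant_id,
                        sess.session_index,
                        sess.condition,
                        sess.task_kind,
                        traj.path_id,
                        k,
                        t,
                        x,
                        y,
                    )
                )
    frame = pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    if covariates_path is not None:
        write_covariates(cohort, covariates_path)
    return path


def write_covariates(cohort: Cohort, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for sess in sorted(cohort.sessions, key=lambda s: s.key):
        if sess.task_kind != "option_generation":
            continue
        for name in sorted(sess.covariates):
            rows.append(
                (sess.participant_id, sess.session_index, name, sess.covariates[name])
            )
    frame = pd.DataFrame(rows, columns=COVARIATE_COLUMNS)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    return path


def read_covariates(path: str | Path) -> dict[tuple[str, int], dict[str, float]]:
    frame = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in COVARIATE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing covariate columns {missing}")
    out: dict[tuple[str, int], dict[str, float]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault((str(row.participant_id), int(row.session_index)), {})[
            str(row.covariate_name)
        ] = float(row.value)
    return out


def read_cohort(
    path: str | Path,
    geometry: TaskGeometry | str | Path | None = None,
    covariates_path: str | Path | None = None,
) -> Cohort:
    """Read a cohort from the flat trajectory CSV.

    ``geometry`` may be a TaskGeometry, a geometry config file, or None
    (task defaults).  Malformed rows and invalid paths are reported with
    row numbers / path ids; nothing is silently dropped.
    """
    path = Path(path)
    calibration = {"pixels_per_mm_x": 1.0, "pixels_per_mm_y": 1.0}
    if geometry is None:
        geom = TaskGeometry()
    elif isinstance(geometry, TaskGeometry):
        geom = geometry
    else:
        geom, calibration = load_geometry(geometry)

    frame = pd.read_csv(path, dtype={"participant_id": str, "path_id": str})
    pixel_input = {"x_px", "y_px"}.issubset(frame.columns)
    required = [
        c
        for c in TRAJECTORY_COLUMNS
        if not (pixel_input and c in ("x_mm", "y_mm"))
    ]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if pixel_input:
        frame = frame.assign(
            x_mm=frame["x_px"] / calibration["pixels_per_mm_x"],
            y_mm=frame["y_px"] / calibration["pixels_per_mm_y"],
        )

    errors: list[str] = []
    sessions: list[Session] = []
    covs = read_covariates(covariates_path) if covariates_path else {}
    sess_cols = ["participant_id", "session_index", "condition", "task_kind"]
    for (pid, sidx, cond, kind), group in frame.groupby(sess_cols, sort=True):
        trajectories = []
        for path_id, rows in group.groupby("path_id", sort=False):
            rows = rows.sort_values("sample_index")
            samples = rows[["t_s", "x_mm", "y_mm"]].to_numpy(dtype=float)
            try:
                traj = RawTrajectory(
                    path_id=str(path_id),
                    samples=samples,
                    onset=float(samples[0, 0]),
                )
            except ValidationError as exc:
                first_row = int(rows.index.min()) + 2  # 1-based incl. header
                errors.append(f"row {first_row}: {exc}")
                continue
            trajectories.append(traj)
        sess = Session(
            participant_id=str(pid),
            session_index=int(sidx),
            condition=str(cond),
            task_kind=str(kind),
            trajectories=trajectories,
            covariates=covs.get((str(pid), int(sidx)), {}),
        )
        sessions.append(sess)
    if errors:
        raise ValidationError(
            f"{path}: {len(errors)} invalid path(s):\n" + "\n".join(errors)
        )
    cohort = Cohort(sessions=sessions, geometry=geom, provenance=f"read from {path.name}")
    cohort.validate()
    return cohort
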