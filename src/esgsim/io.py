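"""Readers and writers for the interchange formats.

* Procedure logs: JSON Lines, one event per line, preceded by a schema-
  versioned header line (``"schema": 1``).
* Trajectories: CSV with header ``t,x,y,z``.
* Score reports: JSON.
* Rosters: CSV mirroring the participant-record fields.
* Meshes: Wavefront OBJ (via trimesh), with an optional region-label sidecar
  CSV ``vertex_id,region``.
* Config: TOML with ``physics`` / ``anatomy`` / ``scoring`` sections; unknown
  keys are rejected.
* Soft-body snapshots: flat CSV of particle positions, or HDF5.

Write→read round trips are value-identical; malformed records raise
:class:`LogParseError` naming the offending line.
"""

from __future__ import annotations

import dataclasses
import json
import math
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import AnatomyConfig, Region, StomachModel
from .cohort import ParticipantRecord
from .kinematics import Trajectory
from .procedure import (
    Bite,
    BleedOnset,
    CinchDeploy,
    Grasp,
    Mark,
    ProcedureLog,
    SessionEnd,
    SutureSetEnd,
)
from .scoring import MetricScore, ScoreReport, ScoringConfig
from .softbody import SoftBody, StepConfig

__all__ = [
    "LOG_SCHEMA_VERSION",
    "LogParseError",
    "write_log",
    "read_log",
    "write_trajectory",
    "read_trajectory",
    "write_report",
    "read_report",
    "read_roster",
    "write_roster",
    "export_mesh_obj",
    "write_region_sidecar",
    "load_config",
    "snapshot_positions",
]

LOG_SCHEMA_VERSION = 1


class LogParseError(ValueError):
    pass


_EVENT_TYPES = {
    "MARK": Mark,
    "GRASP": Grasp,
    "BITE": Bite,
    "SUTURE_SET_END": SutureSetEnd,
    "CINCH_DEPLOY": CinchDeploy,
    "BLEED_ONSET": BleedOnset,
    "SESSION_END": SessionEnd,
}


def _encode_value(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Region):
        return v.value
    if isinstance(v, float) and math.isinf(v):
        return None  # JSON has no Infinity; None round-trips back to inf
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def _event_to_obj(event) -> dict:
    obj = {"type": event.type_tag}
    for f in dataclasses.fields(event):
        obj[f.name] = _encode_value(getattr(event, f.name))
    return obj


def _obj_to_event(obj: dict):
    cls = _EVENT_TYPES[obj["type"]]
    kwargs = {}
    for f in dataclasses.fields(cls):
        v = obj[f.name]
        if f.name in ("tip", "target", "points"):
            v = np.asarray(v, float)
        elif f.name == "wall":
            v = Region(v)
        elif f.name == "nearest_mark_distance" and v is None:
            v = math.inf
        kwargs[f.name] = v
    return cls(**kwargs)


def write_log(log: ProcedureLog, path) -> None:
    path = Path(path)
    header = dict(log.metadata)
    header.setdefault("schema", LOG_SCHEMA_VERSION)
    with path.open("w") as fh:
        fh.write(json.dumps(header) + "\n")
        for event in log.events:
            fh.write(json.dumps(_event_to_obj(event)) + "\n")


def read_log(path) -> ProcedureLog:
    """Parse a JSON Lines procedure log.

    Validates the schema version and per-event structure but not session
    completeness — an unfinished log is readable; the scorer rejects it.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise LogParseError(f"{path}: empty log file")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise LogParseError(f"{path}:1: malformed header: {exc}") from exc
    version = header.get("schema")
    if version != LOG_SCHEMA_VERSION:
        raise LogParseError(
            f"{path}:1: schema version mismatch (got {version!r}, "
            f"expected {LOG_SCHEMA_VERSION})"
        )
    log = ProcedureLog(metadata=header)
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
            event = _obj_to_event(obj)
        except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
            raise LogParseError(f"{path}:{lineno}: malformed event: {exc}") from exc
        log.append(event)
    return log


# ------------------------------------------------------------------ trajectory


def write_trajectory(traj: Trajectory, path) -> None:
    frame = pd.DataFrame(
        {
            "t": traj.times,
            "x": traj.positions[:, 0],
            "y": traj.positions[:, 1],
            "z": traj.positions[:, 2],
        }
    )
    frame.to_csv(path, index=False)


def read_trajectory(path) -> Trajectory:
    frame = pd.read_csv(path)
    missing = {"t", "x", "y", "z"} - set(frame.columns)
    if missing:
        raise LogParseError(f"{path}: trajectory CSV missing columns {sorted(missing)}")
    try:
        return Trajectory(
            frame["t"].to_numpy(float), frame[["x", "y", "z"]].to_numpy(float)
        )
    except ValueError as exc:
        raise LogParseError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------- report


def write_report(report: ScoreReport, path) -> None:
    obj = {
        "metadata": report.metadata,
        "total": report.total,
        "metrics": [dataclasses.asdict(s) for s in report.scores],
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_report(path) -> ScoreReport:
    obj = json.loads(Path(path).read_text())
    scores = [MetricScore(**m) for m in obj["metrics"]]
    return ScoreReport(scores, metadata=obj.get("metadata", {}))


# --------------------------------------------------------------------- roster

_ROSTER_COLUMNS = [
    "id",
    "age",
    "sex",
    "hand_dominance",
    "experience_months",
    "endoscopy_cases",
    "suturing_cases",
]


def read_roster(path) -> list[ParticipantRecord]:
    frame = pd.read_csv(path, dtype={"id": str})
    missing = set(_ROSTER_COLUMNS) - set(frame.columns)
    if missing:
        raise LogParseError(f"{path}: roster CSV missing columns {sorted(missing)}")
    return [
        ParticipantRecord(
            id=row["id"],
            age=int(row["age"]),
            sex=row["sex"],
            hand_dominance=row["hand_dominance"],
            experience_months=int(row["experience_months"]),
            endoscopy_cases=int(row["endoscopy_cases"]),
            suturing_cases=int(row["suturing_cases"]),
        )
        for _, row in frame.iterrows()
    ]


def write_roster(records: list[ParticipantRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records])[_ROSTER_COLUMNS].to_csv(
        path, index=False
    )


# ----------------------------------------------------------------------- mesh


def export_mesh_obj(model: StomachModel, path) -> None:
    import trimesh

    mesh = trimesh.Trimesh(
        vertices=model.surface_vertices(), faces=model.faces, process=False
    )
    mesh.export(str(path))


def write_region_sidecar(model: StomachModel, path) -> None:
    pd.DataFrame(
        {
            "vertex_id": np.arange(len(model.region_labels)),
            "region": [r.value for r in model.region_labels],
        }
    ).to_csv(path, index=False)


# --------------------------------------------------------------------- config

_CONFIG_SECTIONS = {
    "physics": StepConfig,
    "anatomy": AnatomyConfig,
    "scoring": ScoringConfig,
}


def load_config(path) -> dict:
    """Load a TOML config into typed section objects; unknown keys rejected."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - set(_CONFIG_SECTIONS)
    if unknown:
        raise LogParseError(f"{path}: unknown config sections {sorted(unknown)}")
    out = {}
    for section, cls in _CONFIG_SECTIONS.items():
        values = raw.get(section, {})
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(values) - known
        if bad:
            raise LogParseError(
                f"{path}: unknown keys {sorted(bad)} in [{section}]"
            )
        out[section] = cls(**values)
    return out


# ------------------------------------------------------------------ snapshots


def snapshot_positions(body: SoftBody, path, fmt: str = "csv") -> None:
    """Dump particle positions to flat CSV or HDF5."""
    if fmt == "csv":
        pd.DataFrame(body.positions, columns=["x", "y", "z"]).to_csv(path, index=False)
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("positions", data=body.positions)
            fh.create_dataset("velocities", data=body.velocities)
            fh.attrs["time"] = body.time
    else:
        raise ValueError("fmt must be 'csv' or 'hdf5'")
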