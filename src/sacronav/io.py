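"""File formats: meshes, plan/landmark/transform JSON, pose/event JSONL,
YAML trial configuration and CSV reports.

All coordinates are serialised as arrays of three floats in millimetres, in
the document's declared space; no implicit unit conversion anywhere. JSON
documents are schema-validated (unknown fields are rejected loudly). CSV
reports carry a ``#``-comment metadata header echoing the seed so every
output is traceable to its random stream.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .geometry import LandmarkSet, SimilarityTransform, Trajectory
from .guidance import DrillPose, GuidanceEvent
from .phantom import NoiseModel, PhantomParams
from .sensitivity import TrialConfig

__all__ = [
    "PlanDocument",
    "ScrewSpec",
    "read_mesh",
    "write_mesh",
    "load_plan",
    "save_plan",
    "load_landmarks",
    "save_landmarks",
    "load_transform",
    "save_transform",
    "read_pose_stream",
    "write_pose_stream",
    "write_event_log",
    "load_trial_config",
    "write_report_csv",
    "read_report_csv",
]

_MESH_SUFFIXES = {".stl", ".obj", ".ply"}


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ScrewSpec(_StrictModel):
    label: str
    entry: list[float]
    central_aim: list[float]
    diameter: float
    depth: float

    @field_validator("entry", "central_aim")
    @classmethod
    def _three_finite(cls, v):
        if len(v) != 3 or not all(np.isfinite(x) for x in v):
            raise ValueError("coordinates must be 3 finite floats")
        return v

    def to_trajectory(self) -> Trajectory:
        return Trajectory(self.entry, self.central_aim, self.diameter, self.depth)


class LandmarksModel(_StrictModel):
    left_asis: list[float]
    right_asis: list[float]
    symphysis: list[float]

    def to_landmarks(self) -> LandmarkSet:
        return LandmarkSet(self.left_asis, self.right_asis, self.symphysis)


class PlanDocument(_StrictModel):
    """A screw plan: labelled trajectories plus the registration landmarks."""

    version: int = 1
    space: str = "model"
    screws: list[ScrewSpec]
    landmarks: LandmarksModel

    @field_validator("space")
    @classmethod
    def _space(cls, v):
        if v not in ("model", "world"):
            raise ValueError("space must be 'model' or 'world'")
        return v

    @field_validator("screws")
    @classmethod
    def _unique_labels(cls, v):
        labels = [s.label for s in v]
        if len(set(labels)) != len(labels):
            raise ValueError("screw labels must be unique")
        return v

    def trajectories(self) -> dict:
        return {s.label: s.to_trajectory() for s in self.screws}


# -- meshes -------------------------------------------------------------------


def read_mesh(path):
    """Load a triangle mesh (STL/OBJ/PLY), vertices in mm."""
    import trimesh

    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise ValueError(f"unsupported mesh format: {path.suffix!r}")
    try:
        mesh = trimesh.load_mesh(path, file_type=path.suffix.lstrip("."))
    except Exception as e:  # trimesh raises a zoo of types
        raise ValueError(f"failed to parse mesh {path}: {e}") from e
    if mesh is None or not hasattr(mesh, "vertices") or len(mesh.vertices) == 0:
        raise ValueError(f"mesh {path} is empty or unreadable")
    return mesh


def write_mesh(mesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise ValueError(f"unsupported mesh format: {path.suffix!r}")
    mesh.export(path)


# -- JSON documents -----------------------------------------------------------


def load_plan(path) -> PlanDocument:
    with open(path) as f:
        return PlanDocument.model_validate(json.load(f))


def save_plan(doc: PlanDocument, path) -> None:
    with open(path, "w") as f:
        json.dump(doc.model_dump(), f, indent=2)
        f.write("\n")


def plan_from_phantom(phantom, space: str = "model") -> PlanDocument:
    screws = [
        ScrewSpec(
            label=label,
            entry=t.entry.tolist(),
            central_aim=t.central_aim.tolist(),
            diameter=t.diameter,
            depth=t.depth,
        )
        for label, t in phantom.planned_in_order()
    ]
    return PlanDocument(
        space=space,
        screws=screws,
        landmarks=LandmarksModel(**phantom.landmarks.to_dict()),
    )


def load_landmarks(path) -> LandmarkSet:
    with open(path) as f:
        return LandmarksModel.model_validate(json.load(f)).to_landmarks()


def save_landmarks(landmarks: LandmarkSet, path) -> None:
    with open(path, "w") as f:
        json.dump(landmarks.to_dict(), f, indent=2)
        f.write("\n")


class TransformModel(_StrictModel):
    rotation: list[float]
    translation: list[float]
    scale: float
    fre_rms: float | None = None

    @field_validator("rotation")
    @classmethod
    def _nine(cls, v):
        if len(v) != 9:
            raise ValueError("rotation must be 9 row-major floats")
        return v


def load_transform(path) -> SimilarityTransform:
    with open(path) as f:
        m = TransformModel.model_validate(json.load(f))
    return SimilarityTransform.from_dict(m.model_dump())


def save_transform(T: SimilarityTransform, path, fre_rms: float | None = None) -> None:
    d = T.to_dict()
    if fre_rms is not None:
        d["fre_rms"] = float(fre_rms)
    with open(path, "w") as f:
        json.dump(d, f, indent=2)
        f.write("\n")


# -- JSONL streams ------------------------------------------------------------


def read_pose_stream(path) -> list[DrillPose]:
    """Read a JSONL pose stream: one ``{"t", "tip", "dir"}`` object per line."""
    poses = []
    with open(path) as f:
        for lineno, line in enumerate(f, 1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
                poses.append(DrillPose(float(d["t"]), d["tip"], d["dir"]))
            except (KeyError, ValueError, TypeError) as e:
                raise ValueError(f"{path}:{lineno}: malformed pose record: {e}") from e
    return poses


def write_pose_stream(poses, path) -> None:
    with open(path, "w") as f:
        for p in poses:
            f.write(
                json.dumps(
                    {"t": float(p.timestamp), "tip": p.tip.tolist(), "dir": p.direction.tolist()}
                )
                + "\n"
            )


def write_event_log(events, path) -> None:
    with open(path, "w") as f:
        for e in events:
            f.write(json.dumps(e.to_dict()) + "\n")


def read_event_log(path) -> list[GuidanceEvent]:
    events = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if line:
                d = json.loads(line)
                events.append(GuidanceEvent(d["t"], d["event"], d["screw"]))
    return events


# -- YAML trial configuration -------------------------------------------------


def load_trial_config(path, seed_override: int | None = None) -> TrialConfig:
    """Build a :class:`TrialConfig` from a YAML file.

    Recognised top-level keys: ``n_pelves``, ``seed``, ``allow_scale``,
    ``random_world_pose``, ``world_translation_range``, and the nested
    ``noise`` and ``phantom`` parameter blocks.
    """
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ValueError("trial config must be a YAML mapping")
    known = {
        "n_pelves",
        "seed",
        "allow_scale",
        "random_world_pose",
        "world_translation_range",
        "noise",
        "phantom",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    noise = NoiseModel(**(raw.get("noise") or {}))
    phantom = PhantomParams(**(raw.get("phantom") or {}))
    kwargs = {k: raw[k] for k in known - {"noise", "phantom"} if k in raw}
    if seed_override is not None:
        kwargs["seed"] = seed_override
    return TrialConfig(noise=noise, phantom=phantom, **kwargs)


# -- CSV reports --------------------------------------------------------------


def write_report_csv(df: pd.DataFrame, path, seed: int | None = None, **metadata) -> None:
    """Write a table with a ``#`` metadata header (seed, parameter echo)."""
    with open(path, "w") as f:
        if seed is not None:
            f.write(f"# seed={seed}\n")
        for k, v in metadata.items():
            f.write(f"# {k}={v}\n")
        df.to_csv(f, index=False)


def read_report_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
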