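"""Plain-text readers and writers for trials, truth tables and results.

Marker trials are wide CSV (``time`` + ``<landmark>_{x,y,z}`` columns, SI
units) with ``#``-prefixed metadata header lines; signal trials are CSV with
one column per channel; ground truth is a single JSON document.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .emg import SignalTrial
from .kinematics import MarkerTrial
from .synthetic import GroundTruth


def write_marker_csv(trial: MarkerTrial, path: str | Path) -> None:
    path = Path(path)
    names = sorted(trial.landmarks)
    cols = {"time": trial.time}
    for name in names:
        xyz = np.asarray(trial.landmarks[name])
        for k, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = xyz[:, k]
    frame = pd.DataFrame(cols)
    with path.open("w") as fh:
        fh.write(f"# pitch_id: {trial.pitch_id}\n")
        fh.write(f"# handedness: {trial.handedness}\n")
        fh.write("# units: m, s\n")
        frame.to_csv(fh, index=False, float_format="%.9g")


def read_marker_csv(path: str | Path) -> MarkerTrial:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh)
    time = frame["time"].to_numpy(dtype=float)
    landmarks: dict[str, np.ndarray] = {}
    bases = {c[:-2] for c in frame.columns if c.endswith(("_x", "_y", "_z"))}
    for name in sorted(bases):
        landmarks[name] = np.column_stack(
            [frame[f"{name}_{ax}"].to_numpy(dtype=float) for ax in "xyz"]
        )
    return MarkerTrial(
        time,
        landmarks,
        handedness=meta.get("handedness", "right"),
        pitch_id=meta.get("pitch_id", path.stem),
    )


def write_signal_csv(trial: SignalTrial, path: str | Path) -> None:
    path = Path(path)
    frame = pd.DataFrame({"time": trial.time, **trial.channels})
    with path.open("w") as fh:
        fh.write(f"# pitch_id: {trial.pitch_id}\n")
        fh.write("# units: V (EMG), m/s^2 (accel), s\n")
        frame.to_csv(fh, index=False, float_format="%.9g")


def read_signal_csv(path: str | Path) -> SignalTrial:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh)
    time = frame["time"].to_numpy(dtype=float)
    channels = {
        c: frame[c].to_numpy(dtype=float) for c in frame.columns if c != "time"
    }
    return SignalTrial(time, channels, pitch_id=meta.get("pitch_id", path.stem))


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    from dataclasses import asdict

    payload = {
        "participants": truth.participants.to_dict(orient="list"),
        "pitches": truth.pitches.to_dict(orient="list"),
        "spec": asdict(truth.spec) if truth.spec is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1, default=float))


def read_ground_truth(path: str | Path) -> GroundTruth:
    from .synthetic import SessionSpec

    payload = json.loads(Path(path).read_text())
    spec = None
    if payload.get("spec") is not None:
        raw = dict(payload["spec"])
        for key in ("device_offset_range",):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if raw.get("participant_anthro") is not None:
            raw["participant_anthro"] = [tuple(a) for a in raw["participant_anthro"]]
        for key in ("n_participants", "pitches_per_participant", "block_size", "rng_seed"):
            if key in raw:
                raw[key] = int(raw[key])
        for key in ("emg_noise",):
            if key in raw:
                raw[key] = bool(raw[key])
        spec = SessionSpec(**raw)
    return GroundTruth(
        participants=pd.DataFrame(payload["participants"]),
        pitches=pd.DataFrame(payload["pitches"]),
        spec=spec,
    )


def write_angles_csv(pitch_id: str, angles, path: str | Path) -> None:
    """Tidy angles/events CSV: pitch_id, time, variable, value (radians)."""
    names = [
        ("elbow_flexion_extension", angles.elbow[:, 0]),
        ("elbow_ab_adduction", angles.elbow[:, 1]),
        ("elbow_pronation_supination", angles.elbow[:, 2]),
        ("shoulder_plane_of_elevation", angles.shoulder[:, 0]),
        ("shoulder_negative_elevation", angles.shoulder[:, 1]),
        ("shoulder_axial_rotation", angles.shoulder[:, 2]),
    ]
    rows = []
    for variable, series in names:
        rows.append(
            pd.DataFrame(
                {
                    "pitch_id": pitch_id,
                    "time": angles.time,
                    "variable": variable,
                    "value": series,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.9g")
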