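"""CSV / JSON schemas of the on-disk session layout.

All time series are plain RFC-4180 CSV with a header row, UTF-8, '.'
decimal, time in seconds from trial start as the first column and an
integer ``phase`` column; manifests and reports are JSON.  Writers are
deterministic (fixed float format, sorted keys), so a rerun from the same
configuration is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MUSCLES, TrialData, TaskReference

FLOAT_FORMAT = "%.9g"

__all__ = ["write_trial", "read_trial", "read_manifest", "write_force_trace"]


def _pose_frame(trial: TrialData) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": trial.pose_time,
            "grasp_ratio": trial.grasp,
            "pronation_deg": trial.pronation,
            "phase": trial.pose_phase,
        }
    )


def _imu_frame(trial: TrialData) -> pd.DataFrame:
    data = {"time_s": trial.imu_time}
    data.update(trial.imu)
    data["phase"] = trial.imu_phase
    return pd.DataFrame(data)


def _emg_frame(trial: TrialData) -> pd.DataFrame:
    data = {"time_s": trial.emg_time}
    for j, muscle in enumerate(MUSCLES[: trial.emg.shape[1]]):
        data[muscle] = trial.emg[:, j]
    data["phase"] = trial.emg_phase
    return pd.DataFrame(data)


def write_trial(out_dir, trial: TrialData) -> dict[str, Path]:
    """Write the pose/imu/emg CSVs of one trial; returns the paths."""
    subject_dir = Path(out_dir) / f"subject_{trial.subject_id:02d}"
    subject_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    frames = {"pose": _pose_frame(trial)}
    if len(trial.imu_time):
        frames["imu"] = _imu_frame(trial)
    if len(trial.emg_time):
        frames["emg"] = _emg_frame(trial)
    for stream, frame in frames.items():
        path = subject_dir / f"trial_{trial.trial_id:02d}_{stream}.csv"
        frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
        paths[stream] = path
    return paths


def read_manifest(data_dir) -> dict:
    path = Path(data_dir) / "manifest.json"
    return json.loads(path.read_text())


def read_trial(data_dir, entry: dict) -> TrialData:
    """Load one trial back from its manifest entry."""
    base = Path(data_dir)
    pose = pd.read_csv(base / entry["files"]["pose"])
    ref = TaskReference(
        grasp_ref=entry["grasp_ref"],
        pronation_ref=entry["pronation_ref"],
        phase_durations=tuple(entry["phase_durations"]),
    )
    imu_time = np.empty(0)
    imu: dict = {}
    imu_phase = np.empty(0, dtype=int)
    if "imu" in entry["files"]:
        frame = pd.read_csv(base / entry["files"]["imu"])
        imu_time = frame["time_s"].to_numpy()
        imu_phase = frame["phase"].to_numpy()
        imu = {
            c: frame[c].to_numpy()
            for c in frame.columns
            if c not in ("time_s", "phase")
        }
    emg_time = np.empty(0)
    emg = np.empty((0, len(MUSCLES)))
    emg_phase = np.empty(0, dtype=int)
    if "emg" in entry["files"]:
        frame = pd.read_csv(base / entry["files"]["emg"])
        emg_time = frame["time_s"].to_numpy()
        emg_phase = frame["phase"].to_numpy()
        emg = frame[[c for c in MUSCLES if c in frame.columns]].to_numpy()
    return TrialData(
        subject_id=entry["subject"],
        trial_id=entry["trial"],
        condition=entry["condition"],
        seed=entry["seed"],
        reference=ref,
        pose_time=pose["time_s"].to_numpy(),
        grasp=pose["grasp_ratio"].to_numpy(),
        pronation=pose["pronation_deg"].to_numpy(),
        pose_phase=pose["phase"].to_numpy(),
        imu_time=imu_time, imu=imu, imu_phase=imu_phase,
        emg_time=emg_time, emg=emg, emg_phase=emg_phase,
        events=entry["events"],
    )


def write_force_trace(path, time_s, F_a, F_b, e_p, e_b_mm) -> None:
    """Export a rendered force trace in the standard column layout."""
    pd.DataFrame(
        {
            "time_s": time_s,
            "F_a_N": F_a,
            "F_b_N": F_b,
            "e_p": e_p,
            "e_b_mm": e_b_mm,
        }
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)
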