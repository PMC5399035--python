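"""Cohort and result serialisation.

A cohort on disk is one directory per subject holding the sensor epochs in
HDF5 (datasets ``data`` [epochs × channels × samples], ``rate``,
``channel_positions``, ``channel_orientations``), a single top-level
``covariates.csv`` (subject_id, group, age, scores, hippocampal volume)
and the generator's ``ground_truth.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocessing import SensorEpochs
from .synthetic import SubjectRecord

COVARIATES_FILE = "covariates.csv"
GROUND_TRUTH_FILE = "ground_truth.json"
EPOCHS_FILE = "sensor_epochs.h5"


def write_sensor_epochs(path: Path | str, epochs: SensorEpochs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip")
        f.create_dataset("rate", data=float(epochs.rate))
        f.create_dataset("channel_positions", data=epochs.channel_positions)
        f.create_dataset("channel_orientations",
                         data=epochs.channel_orientations)
        f.create_dataset("channel_names",
                         data=np.array(epochs.channel_names, dtype="S"))


def read_sensor_epochs(path: Path | str) -> SensorEpochs:
    with h5py.File(path, "r") as f:
        return SensorEpochs(
            data=f["data"][()], rate=float(f["rate"][()]),
            channel_positions=f["channel_positions"][()],
            channel_orientations=f["channel_orientations"][()],
            channel_names=[n.decode() for n in f["channel_names"][()]])


def write_cohort(directory: Path | str, subjects: list[SubjectRecord],
                 report: dict | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        sdir = directory / s.subject_id
        sdir.mkdir(exist_ok=True)
        write_sensor_epochs(sdir / EPOCHS_FILE, s.sensor_epochs)
        row = {"subject_id": s.subject_id, "group": s.group, "age": s.age,
               "hippocampal_volume": s.hippocampal_volume,
               "n_epochs": s.n_epochs}
        row.update(s.scores)
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / COVARIATES_FILE, index=False)
    if report is not None:
        with open(directory / GROUND_TRUTH_FILE, "w") as f:
            json.dump(report, f, indent=1)


def read_cohort(directory: Path | str) -> tuple[list[SubjectRecord], dict | None]:
    directory = Path(directory)
    cov = pd.read_csv(directory / COVARIATES_FILE)
    score_cols = [c for c in cov.columns
                  if c not in {"subject_id", "group", "age",
                               "hippocampal_volume", "n_epochs"}]
    subjects = []
    for _, row in cov.iterrows():
        sid = row["subject_id"]
        epochs = read_sensor_epochs(directory / sid / EPOCHS_FILE)
        subjects.append(SubjectRecord(
            subject_id=sid, group=row["group"], age=float(row["age"]),
            scores={c: float(row[c]) for c in score_cols},
            hippocampal_volume=float(row["hippocampal_volume"]),
            sensor_epochs=epochs, n_epochs=int(row.get("n_epochs", 0))))
    gt_path = directory / GROUND_TRUTH_FILE
    report = json.loads(gt_path.read_text()) if gt_path.exists() else None
    return subjects, report
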