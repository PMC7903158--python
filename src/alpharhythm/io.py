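"""Dataset container: HDF5 for arrays, CSV for tables.

A dataset directory holds one ``dataset.h5`` with per-participant groups
(``participant_00``, ...) containing the epoch array, time axis, layout
table and ground-truth parameters, plus per-participant ``schedule_XX.csv``
and ``behavior_XX.csv`` files with documented column names. The container
carries a format tag and version; mismatches raise a versioned
:class:`~alpharhythm.errors.SchemaError` instead of crashing downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import SchemaError
from .simulate import (
    SCHEDULE_COLUMNS,
    GeneratorParams,
    SensorLayout,
    SimulatedRecording,
)

__all__ = ["ParticipantData", "write_dataset", "read_dataset"]

FORMAT_TAG = "alpharhythm-dataset"
FORMAT_VERSION = 1

BEHAVIOR_COLUMNS = ["trial_id", "correct", "rt"]


@dataclass
class ParticipantData:
    """One participant's recording plus behavior table."""

    recording: SimulatedRecording
    behavior: pd.DataFrame


def write_dataset(path, participants: list[ParticipantData]) -> Path:
    """Write a cohort to a dataset directory; returns the directory path."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    with h5py.File(root / "dataset.h5", "w") as h5:
        h5.attrs["format"] = FORMAT_TAG
        h5.attrs["version"] = FORMAT_VERSION
        h5.attrs["n_participants"] = len(participants)
        for pid, part in enumerate(participants):
            rec = part.recording
            grp = h5.create_group(f"participant_{pid:02d}")
            grp.create_dataset("epochs", data=rec.epochs, compression="gzip")
            grp.create_dataset("time_axis", data=rec.time_axis)
            layout = rec.layout.to_frame()
            grp.create_dataset(
                "layout",
                data=np.array(
                    [
                        [row.position, row.hemisphere, row.chan_1, row.chan_2]
                        for row in layout.itertuples(index=False)
                    ],
                    dtype=h5py.string_dtype(),
                ),
            )
            gt = {
                k: (v if not isinstance(v, dict) else v)
                for k, v in rec.ground_truth.__dict__.items()
            }
            grp.attrs["ground_truth"] = json.dumps(gt)
    for pid, part in enumerate(participants):
        part.recording.schedule.to_csv(root / f"schedule_{pid:02d}.csv", index=False)
        part.behavior.to_csv(root / f"behavior_{pid:02d}.csv", index=False)
    return root


def _read_schedule(path: Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(SCHEDULE_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"schedule {path.name} lacks columns {sorted(missing)}")
    frame["cued_position"] = frame["cued_position"].astype("Int64")
    frame["is_valid"] = frame["is_valid"].astype("boolean")
    return frame[SCHEDULE_COLUMNS]


def read_dataset(path) -> list[ParticipantData]:
    """Read a dataset directory written by :func:`write_dataset`."""
    root = Path(path)
    h5_path = root / "dataset.h5"
    if not h5_path.exists():
        raise SchemaError(f"no dataset.h5 under {root}")
    try:
        h5 = h5py.File(h5_path, "r")
    except OSError as exc:
        raise SchemaError(f"unreadable or truncated container {h5_path}: {exc}") from exc
    with h5:
        tag = h5.attrs.get("format")
        version = h5.attrs.get("version")
        if tag != FORMAT_TAG or version != FORMAT_VERSION:
            raise SchemaError(
                f"container format {tag!r} version {version!r} does not match "
                f"{FORMAT_TAG!r} version {FORMAT_VERSION}"
            )
        n = int(h5.attrs["n_participants"])
        participants = []
        for pid in range(n):
            key = f"participant_{pid:02d}"
            if key not in h5:
                raise SchemaError(f"missing group {key}")
            grp = h5[key]
            layout_rows = [
                [s.decode() if isinstance(s, bytes) else str(s) for s in row]
                for row in grp["layout"][()]
            ]
            layout = SensorLayout(
                positions=tuple(r[0] for r in layout_rows),
                hemispheres=tuple(r[1] for r in layout_rows),
            )
            gt_raw = json.loads(grp.attrs["ground_truth"])
            if "rt_params" in gt_raw:
                gt_raw["rt_params"] = {
                    k: tuple(v) for k, v in gt_raw["rt_params"].items()
                }
            ground_truth = GeneratorParams(**gt_raw)
            schedule = _read_schedule(root / f"schedule_{pid:02d}.csv")
            behavior = pd.read_csv(root / f"behavior_{pid:02d}.csv")
            missing = set(BEHAVIOR_COLUMNS) - set(behavior.columns)
            if missing:
                raise SchemaError(f"behavior table lacks columns {sorted(missing)}")
            recording = SimulatedRecording(
                epochs=grp["epochs"][()],
                time_axis=grp["time_axis"][()],
                schedule=schedule,
                layout=layout,
                ground_truth=ground_truth,
            )
            participants.append(
                ParticipantData(recording=recording, behavior=behavior)
            )
    return participants
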