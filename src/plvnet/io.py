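"""Epoch container and behavioral-log serialization.

One directory per subject: ``data.f32`` holds the little-endian float32
epoch array (channels x samples x trials, C order) and ``meta.json`` the
sidecar (labels, sampling rate, time axis, trial table, group).  Behavioral
logs are a single tidy CSV per cohort.  Epoched recordings from standard
EEG formats (BrainVision, EDF+) can be imported through mne.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import BehavioralRecord, EpochSet

__all__ = [
    "write_epoch_set",
    "read_epoch_set",
    "write_cohort",
    "read_cohort",
    "epochs_from_mne",
]


def write_epoch_set(epochs: EpochSet, directory: str | Path) -> Path:
    """Write one subject's epochs to ``directory`` (created if needed)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    data = np.ascontiguousarray(epochs.data, dtype="<f4")
    (d / "data.f32").write_bytes(data.tobytes())
    meta = {
        "subject_id": epochs.subject_id,
        "group": epochs.group,
        "shape": list(epochs.data.shape),
        "fs": epochs.fs,
        "time_ms": epochs.time_ms.tolist(),
        "channel_labels": list(epochs.channel_labels),
        "trial_table": epochs.trial_table.to_dict(orient="list"),
        "info": epochs.info,
    }
    (d / "meta.json").write_text(json.dumps(meta))
    return d


def read_epoch_set(directory: str | Path) -> EpochSet:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    shape = tuple(meta["shape"])
    data = np.frombuffer((d / "data.f32").read_bytes(), dtype="<f4").reshape(shape)
    return EpochSet(
        subject_id=meta["subject_id"],
        group=meta["group"],
        data=data.copy(),
        time_ms=np.asarray(meta["time_ms"], float),
        channel_labels=tuple(meta["channel_labels"]),
        fs=float(meta["fs"]),
        trial_table=pd.DataFrame(meta["trial_table"]),
        info=meta.get("info", {}),
    )


def write_cohort(
    cohort: list[tuple[EpochSet, BehavioralRecord]], directory: str | Path
) -> Path:
    """Write a whole cohort: one subdirectory per subject plus behavior.csv."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    frames = []
    for epochs, behavior in cohort:
        write_epoch_set(epochs, d / epochs.subject_id)
        t = behavior.trials.copy()
        t.insert(0, "subject_id", behavior.subject_id)
        t.insert(1, "group", behavior.group)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(d / "behavior.csv", index=False)
    return d


def read_cohort(directory: str | Path) -> list[tuple[EpochSet, BehavioralRecord]]:
    d = Path(directory)
    behav = pd.read_csv(d / "behavior.csv")
    out = []
    for sub_dir in sorted(p for p in d.iterdir() if (p / "meta.json").exists()):
        epochs = read_epoch_set(sub_dir)
        t = behav[behav["subject_id"] == epochs.subject_id].reset_index(drop=True)
        record = BehavioralRecord(
            subject_id=epochs.subject_id,
            group=epochs.group,
            trials=t.drop(columns=["subject_id", "group"]),
        )
        out.append((epochs, record))
    return out


def epochs_from_mne(mne_epochs, subject_id: str, group: str) -> EpochSet:
    """Convert an ``mne.Epochs``/``EpochsArray`` to the pipeline container.

    Works for any source mne can read (BrainVision, EDF+, FIF...); the
    input is assumed already cleaned and CSD-transformed.  Times are
    re-expressed in ms; every epoch is marked valid.
    """
    data = mne_epochs.get_data(copy=True)  # epochs x channels x samples
    n_ep = data.shape[0]
    table = pd.DataFrame(
        {"trial": np.arange(n_ep), "side": ["unknown"] * n_ep, "valid": True}
    )
    return EpochSet(
        subject_id=subject_id,
        group=group,
        data=np.ascontiguousarray(data.transpose(1, 2, 0), dtype=np.float32),
        time_ms=np.asarray(mne_epochs.times, float) * 1000.0,
        channel_labels=tuple(mne_epochs.ch_names),
        fs=float(mne_epochs.info["sfreq"]),
        trial_table=table,
    )
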