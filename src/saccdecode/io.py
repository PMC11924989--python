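"""Serialization: HDF5 containers for recordings/epochs, TSV gaze, CSV tables."""

from __future__ import annotations

import io as _io
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .eeg import ContinuousRecording
from .epochs import EpochSet
from .gaze import GazeTrace


def save_recording(path: str | Path, rec: ContinuousRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=rec.eeg, compression="gzip", compression_opts=1)
        f.attrs["rate_hz"] = rec.rate_hz
        f.attrs["channel_names"] = np.array(rec.channel_names, dtype="S8")
        g = f.create_group("events")
        for col in rec.events.columns:
            g.create_dataset(col, data=rec.events[col].to_numpy())


def load_recording(path: str | Path) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        events = pd.DataFrame({k: f["events"][k][()] for k in f["events"]})
        return ContinuousRecording(
            eeg=f["eeg"][()],
            rate_hz=float(f.attrs["rate_hz"]),
            events=events[["sample_index", "event_code", "trial_id"]],
            channel_names=[s.decode() for s in f.attrs["channel_names"]],
        )


def save_epochs(path: str | Path, ep: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ep.data, compression="gzip", compression_opts=1)
        f.create_dataset("times", data=ep.times)
        f.attrs["subject_id"] = ep.subject_id
        f.attrs["meta_csv"] = ep.meta.to_csv(index=False)


def load_epochs(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        meta = pd.read_csv(_io.StringIO(f.attrs["meta_csv"]))
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            meta=meta,
            subject_id=str(f.attrs["subject_id"]),
        )


def save_gaze(path: str | Path, gaze: GazeTrace) -> None:
    gaze.to_frame().to_csv(path, sep="\t", index=False, float_format="%.5f")


def load_gaze(path: str | Path, rate_hz: float = 1000.0) -> GazeTrace:
    df = pd.read_csv(path, sep="\t")
    return GazeTrace(
        rate_hz=rate_hz,
        x=df.x_dva.to_numpy(),
        y=df.y_dva.to_numpy(),
        blink=df.blink_flag.to_numpy().astype(bool),
    )


def results_frame(series_by_condition: dict) -> pd.DataFrame:
    """Long-format decoding results: subject, condition, time_ms, accuracy, n_test."""
    frames = [s.to_frame() for group in series_by_condition.values() for s in group]
    return pd.concat(frames, ignore_index=True)
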