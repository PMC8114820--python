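"""Plain-text exchange formats.

Recordings are stored as one delimited matrix per recording (rows =
samples, columns = channels, header row with channel ids) plus a JSON
sidecar holding the sampling rate, channel metadata, markers, and
subject/session identity.  Epoch sets are stored as one matrix per
modality (rows = trials, columns = channel-major flattened samples) with a
JSON sidecar.  Feature tables are CSV with a trailing "label" column, and
class-weight matrices are CSV with one row per class.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .features import FeatureTable
from .synth import ChannelInfo, Marker, RawRecording

__all__ = [
    "write_recording", "read_recording",
    "write_epochs", "read_epochs",
    "write_table", "read_table",
    "write_weights", "read_weights",
]


def _rec_stem(rec: RawRecording) -> str:
    modality = rec.channels[0].modality if rec.channels else "data"
    return f"sub{rec.subject:02d}_ses{rec.session:02d}_{modality}"


def write_recording(rec: RawRecording, out_dir, stem: str | None = None) -> Path:
    """Write a recording as ``<stem>.tsv`` + ``<stem>.json``; returns the stem path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or _rec_stem(rec)
    header = "\t".join(ch.id for ch in rec.channels)
    np.savetxt(out_dir / f"{stem}.tsv", rec.data.T, delimiter="\t",
               header=header, comments="", fmt="%.10g")
    meta = {
        "fs": rec.fs,
        "subject": rec.subject,
        "session": rec.session,
        "channels": [dataclasses.asdict(ch) for ch in rec.channels],
        "markers": [{"onset": m.onset, "label": m.label} for m in rec.markers],
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    return out_dir / stem


def read_recording(stem_path) -> RawRecording:
    """Read a recording written by :func:`write_recording` (path without suffix)."""
    stem_path = Path(stem_path)
    meta = json.loads(stem_path.with_suffix(".json").read_text())
    data = np.loadtxt(stem_path.with_suffix(".tsv"), delimiter="\t",
                      skiprows=1, ndmin=2).T
    return RawRecording(
        data=data,
        fs=meta["fs"],
        channels=[ChannelInfo(**ch) for ch in meta["channels"]],
        markers=[Marker(onset=m["onset"], label=m["label"])
                 for m in meta["markers"]],
        subject=meta["subject"],
        session=meta["session"],
    )


def write_epochs(epochs: EpochSet, out_dir, stem: str) -> Path:
    """Write an epoch archive: trials x (channel-major samples) matrix + sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    flat = epochs.data.reshape(epochs.n_trials,
                               epochs.n_channels * epochs.n_samples)
    np.savetxt(out_dir / f"{stem}.tsv", flat, delimiter="\t", fmt="%.10g")
    meta = {
        "fs": epochs.fs, "t0": epochs.t0, "modality": epochs.modality,
        "n_channels": epochs.n_channels, "n_samples": epochs.n_samples,
        "labels": epochs.labels.tolist(), "channel_ids": epochs.channel_ids,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    return out_dir / stem


def read_epochs(stem_path) -> EpochSet:
    stem_path = Path(stem_path)
    meta = json.loads(stem_path.with_suffix(".json").read_text())
    flat = np.loadtxt(stem_path.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    data = flat.reshape(len(meta["labels"]), meta["n_channels"],
                        meta["n_samples"])
    return EpochSet(data=data, fs=meta["fs"], t0=meta["t0"],
                    labels=np.asarray(meta["labels"]),
                    channel_ids=meta["channel_ids"],
                    modality=meta["modality"])


def write_table(table: FeatureTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_dataframe().to_csv(path, index=False)
    return path


def read_table(path, name: str = "") -> FeatureTable:
    return FeatureTable.from_dataframe(pd.read_csv(path), name=name or Path(path).stem)


def write_weights(cw, path) -> Path:
    """Class-weight matrix as CSV: one row per class, one column per feature."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(cw.w, index=[f"class_{c}" for c in cw.class_labels])
    df.to_csv(path)
    return path


def read_weights(path) -> np.ndarray:
    return pd.read_csv(path, index_col=0).to_numpy(float)
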