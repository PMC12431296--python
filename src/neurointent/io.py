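"""File adapters: EEG recordings, epoch containers, features, models, reports.

Formats
-------
* EDF/GDF recordings (events from the annotation track) via :mod:`mne`
  (optional dependency, imported lazily).
* Plain numeric matrices: ``.npz`` or ``.csv`` with a JSON sidecar carrying
  channel names, sampling rate and events.
* Epoch sets: HDF5 containers (data, labels, channel names, fs).
* Models: joblib archives with a format-version field.
* Score tables and task reports: CSV.

Malformed inputs raise typed errors naming the offending record.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import joblib
import numpy as np

from .preproc import EEGRecording, EpochSet

ARCHIVE_VERSION = 1


class FormatError(ValueError):
    """A file failed validation against its declared format."""


def read_raw_edf(path, label_map: dict[str, int] | None = None,
                 channel_rename: dict[str, str] | None = None) -> EEGRecording:
    """Read an EDF/GDF recording; annotations become (onset, label) events.

    ``label_map`` maps annotation descriptions to class ids 0..3 (required to
    produce events); ``channel_rename`` maps recorded electrode names to
    10-10 labels (e.g. dataset channel indices to standard names).
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF/GDF requires the 'mne' package "
                          "(install the 'eeg-io' extra)") from exc
    path = str(path)
    reader = mne.io.read_raw_gdf if path.lower().endswith(".gdf") else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    names = list(raw.ch_names)
    if channel_rename:
        names = [channel_rename.get(n, n) for n in names]
    fs = float(raw.info["sfreq"])
    events = []
    if label_map:
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
            if desc in label_map:
                events.append((int(round(onset * fs)), int(label_map[desc])))
    return EEGRecording(raw.get_data() * 1e6, names, fs, events)


def read_raw_matrix(path) -> EEGRecording:
    """Read a ``.npz``/``.csv`` numeric matrix with a ``.json`` sidecar.

    The sidecar (same stem, ``.json`` suffix) must provide ``channel_names``,
    ``fs`` and optionally ``events`` as ``[[onset_sample, label], ...]``.
    """
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in ("channel_names", "fs"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} lacks required key {key!r}")
    if path.suffix == ".npz":
        with np.load(path) as z:
            if "samples" not in z:
                raise FormatError(f"{path} lacks a 'samples' array")
            samples = z["samples"]
    else:
        samples = np.loadtxt(path, delimiter=",", ndmin=2)
    events = [tuple(e) for e in meta.get("events", [])]
    return EEGRecording(samples, meta["channel_names"], float(meta["fs"]), events)


def write_raw_matrix(path, rec: EEGRecording) -> None:
    path = Path(path)
    np.savez(path, samples=rec.samples)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"channel_names": rec.channel_names, "fs": rec.fs,
                   "events": [list(e) for e in rec.events]}, fh)


def write_epochs(path, epochs: EpochSet) -> None:
    """HDF5 epoch container: data, labels, channel names, fs."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("channel_names",
                         data=np.array(epochs.channel_names, dtype="S"))
        f.attrs["fs"] = epochs.fs
        f.attrs["version"] = ARCHIVE_VERSION


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        for key in ("data", "labels", "channel_names"):
            if key not in f:
                raise FormatError(f"epochs container {path} lacks {key!r}")
        data = f["data"][...]
        labels = f["labels"][...]
        names = [n.decode() for n in f["channel_names"][...]]
        fs = float(f.attrs.get("fs", 250.0))
    if data.ndim != 3 or data.shape[0] != len(labels):
        raise FormatError(f"epochs container {path} is inconsistent")
    return EpochSet(data, labels, names, fs)


def save_model(path, model, kind: str) -> None:
    """Versioned model archive (joblib)."""
    joblib.dump({"version": ARCHIVE_VERSION, "kind": kind, "model": model}, path)


def load_model(path, kind: str | None = None):
    payload = joblib.load(path)
    if not isinstance(payload, dict) or "model" not in payload:
        raise FormatError(f"{path} is not a model archive")
    if payload.get("version") != ARCHIVE_VERSION:
        raise FormatError(f"{path}: unsupported archive version "
                          f"{payload.get('version')}")
    if kind is not None and payload.get("kind") != kind:
        raise FormatError(f"{path} holds a {payload.get('kind')!r} model, "
                          f"expected {kind!r}")
    return payload["model"]
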