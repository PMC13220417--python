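"""Recording container readers and writers.

Canonical container is HDF5 (dataset ``data`` of shape channels x
samples, attributes ``fs`` and ``channel_labels``, optional JSON
``metadata``); CSV (one column per channel plus a ``<path>.json`` sidecar
holding at least ``fs``) is kept for tiny fixtures, and EDF is supported
read-only for interoperability with clinical/ephys tooling.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError
from .preprocess import Recording


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a Recording; format chosen from the file suffix (.h5/.csv)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("data", data=recording.data)
            ds.attrs["fs"] = recording.fs
            ds.attrs["channel_labels"] = [str(l) for l in recording.channel_labels]
            ds.attrs["metadata"] = json.dumps(recording.metadata, default=str)
    elif path.suffix.lower() == ".csv":
        df = pd.DataFrame(recording.data.T, columns=recording.channel_labels)
        df.to_csv(path, index=False)
        sidecar = {"fs": recording.fs,
                   "channel_labels": list(recording.channel_labels),
                   "metadata": recording.metadata}
        Path(str(path) + ".json").write_text(
            json.dumps(sidecar, indent=2, default=str))
    else:
        raise FormatError(f"unsupported output format {path.suffix!r}")
    return path


def read_recording(path: str | Path) -> Recording:
    """Read a Recording from HDF5, CSV (+ JSON sidecar) or EDF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return _read_hdf5(path)
    if suffix == ".csv":
        return _read_csv(path)
    if suffix == ".edf":
        return _read_edf(path)
    raise FormatError(f"unsupported container format {suffix!r}")


def _read_hdf5(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise FormatError(f"{path}: missing dataset 'data'")
        ds = f["data"]
        if "fs" not in ds.attrs:
            raise FormatError(f"{path}: missing 'fs' attribute")
        data = ds[()]
        if data.ndim != 2:
            raise FormatError(f"{path}: 'data' must be 2-D channels x samples")
        labels = [str(l) for l in ds.attrs.get("channel_labels", [])]
        metadata = json.loads(ds.attrs.get("metadata", "{}"))
        return Recording(data=data, fs=float(ds.attrs["fs"]),
                         channel_labels=labels, metadata=metadata)


def _read_csv(path: Path) -> Recording:
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FormatError(
            f"{path}: missing sidecar {sidecar_path.name} with 'fs' metadata")
    sidecar = json.loads(sidecar_path.read_text())
    if "fs" not in sidecar:
        raise FormatError(f"{sidecar_path}: missing 'fs'")
    df = pd.read_csv(path)
    labels = sidecar.get("channel_labels", list(df.columns))
    return Recording(data=df.to_numpy(dtype=float).T, fs=float(sidecar["fs"]),
                     channel_labels=[str(l) for l in labels],
                     metadata=sidecar.get("metadata", {}))


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        metadata={"source": str(path), "format": "edf"},
    )
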