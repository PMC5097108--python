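"""Reading and writing recordings, event tables and connectivity matrices.

The interchange format for recordings is delimited text: one column per
channel with a header row of channel labels, preceded by comment lines
carrying the sampling rate and condition.  EDF files are read through MNE.
Connectivity-matrix stacks are stored as a compressed ``.npz`` container
with a JSON index manifest next to it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import ConnectivityMatrix, MultichannelRecording

__all__ = [
    "write_recording_text",
    "read_recording_text",
    "read_recording_edf",
    "read_recording",
    "read_events",
    "write_matrix_text",
    "read_matrix_text",
    "save_matrix_stack",
    "load_matrix_stack",
]


def write_recording_text(recording: MultichannelRecording, path: str | Path) -> None:
    """Write a recording as tab-separated text (samples × channels)."""
    path = Path(path)
    header = [f"# fs={recording.fs}"]
    if recording.condition:
        header.append(f"# condition={recording.condition}")
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        fh.write("\t".join(recording.channel_labels) + "\n")
        np.savetxt(fh, recording.samples.T, fmt="%.6f", delimiter="\t")


def read_recording_text(path: str | Path) -> MultichannelRecording:
    path = Path(path)
    fs: Optional[float] = None
    condition: Optional[str] = None
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            key, _, value = line[1:].strip().partition("=")
            if key.strip() == "fs":
                fs = float(value)
            elif key.strip() == "condition":
                condition = value.strip()
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=' header line")
    df = pd.read_csv(path, sep="\t", skiprows=n_comment)
    return MultichannelRecording(
        df.to_numpy().T, fs=fs, channel_labels=list(df.columns), condition=condition
    )


def read_recording_edf(path: str | Path, condition: Optional[str] = None) -> MultichannelRecording:
    """Read an EDF recording via MNE (values converted from volts to µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return MultichannelRecording(
        raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        condition=condition,
    )


def read_recording(path: str | Path, condition: Optional[str] = None) -> MultichannelRecording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_recording_edf(path, condition=condition)
    rec = read_recording_text(path)
    if condition is not None:
        rec.condition = condition
    return rec


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a trial table (columns: onset_sample, condition, correct, ...)."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset_sample", "correct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: events table lacks columns {sorted(missing)}")
    df["correct"] = df["correct"].astype(bool)
    return df


def write_matrix_text(matrix: "ConnectivityMatrix | np.ndarray", path: str | Path) -> None:
    W = matrix.weights if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    np.savetxt(path, W, fmt="%.8f", delimiter="\t")


def read_matrix_text(path: str | Path) -> ConnectivityMatrix:
    return ConnectivityMatrix(np.loadtxt(path, delimiter="\t"))


def save_matrix_stack(
    matrices: Sequence[ConnectivityMatrix],
    path: str | Path,
    meta: Optional[dict] = None,
) -> None:
    """Store a matrix sequence as ``.npz`` plus a JSON index manifest."""
    path = Path(path)
    arrays = {f"m{k:04d}": m.weights for k, m in enumerate(matrices)}
    np.savez_compressed(path, **arrays)
    manifest = {
        "n_matrices": len(matrices),
        "epoch_indices": [m.epoch_index for m in matrices],
        "keys": sorted(arrays),
    }
    if meta:
        manifest.update(meta)
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def load_matrix_stack(path: str | Path) -> list[ConnectivityMatrix]:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as data:
        return [
            ConnectivityMatrix(data[key], epoch_index=idx)
            for key, idx in zip(manifest["keys"], manifest["epoch_indices"])
        ]
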