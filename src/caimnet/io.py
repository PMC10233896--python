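"""File formats: HDF5/CSV recordings, event lists, matrices, ground truth.

Traces travel as HDF5 (datasets ``/traces`` frames x ROIs, ``/positions``,
``/labels``; attribute ``fs_hz``) or as a wide CSV whose first column is
``time_s``. Everything else is plain text: event lists, edge lists and dense
matrices as CSV, metrics as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import FluorescenceRecording
from .synth import SyntheticGroundTruth

__all__ = [
    "save_recording",
    "load_recording",
    "save_ground_truth",
    "load_ground_truth_adjacency",
    "save_event_list",
    "load_event_list",
    "save_matrix",
    "load_matrix",
    "save_json",
]


def save_recording(rec: FluorescenceRecording, path: str | Path) -> Path:
    """Write a recording; format chosen by extension (.h5/.hdf5 or .csv)."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("traces", data=rec.traces)
            f.create_dataset("positions", data=rec.positions)
            if rec.labels is not None:
                f.create_dataset(
                    "labels", data=np.array(rec.labels, dtype=h5py.string_dtype())
                )
            f.create_dataset(
                "roi_ids", data=np.array(rec.roi_ids, dtype=h5py.string_dtype())
            )
            f.attrs["fs_hz"] = rec.fs_hz
    elif path.suffix == ".csv":
        df = pd.DataFrame(rec.traces, columns=rec.roi_ids)
        df.insert(0, "time_s", rec.times_s)
        df.to_csv(path, index=False)
        pos = pd.DataFrame(rec.positions, columns=["x_um", "y_um"])
        pos.insert(0, "roi_id", rec.roi_ids)
        if rec.labels is not None:
            pos["label"] = rec.labels
        pos.to_csv(path.with_suffix(".positions.csv"), index=False)
    else:
        raise ValueError(f"unsupported recording format {path.suffix!r}")
    return path


def load_recording(path: str | Path, fmt: str | None = None) -> FluorescenceRecording:
    """Load a recording written by :func:`save_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or ("hdf5" if path.suffix in {".h5", ".hdf5"} else "csv")
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "fs_hz" not in f.attrs:
                raise ValueError(f"{path}: missing fs_hz attribute")
            traces = np.asarray(f["traces"])
            positions = np.asarray(f["positions"])
            labels = (
                [s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"]]
                if "labels" in f
                else None
            )
            roi_ids = (
                [s.decode() if isinstance(s, bytes) else str(s) for s in f["roi_ids"]]
                if "roi_ids" in f
                else []
            )
            fs = float(f.attrs["fs_hz"])
        return FluorescenceRecording(
            traces=traces, fs_hz=fs, positions=positions,
            roi_ids=roi_ids, labels=labels,
        )
    if fmt == "csv":
        df = pd.read_csv(path)
        if "time_s" not in df.columns:
            raise ValueError(f"{path}: missing required 'time_s' column")
        times = df["time_s"].to_numpy(dtype=float)
        if times.size < 2:
            raise ValueError(f"{path}: need at least two frames")
        traces = df.drop(columns="time_s")
        non_numeric = [
            c for c in traces.columns
            if not np.issubdtype(traces[c].dtype, np.number)
        ]
        if non_numeric:
            raise ValueError(f"{path}: non-numeric trace column(s) {non_numeric}")
        fs = 1.0 / float(np.median(np.diff(times)))
        pos_path = path.with_suffix(".positions.csv")
        labels = None
        if pos_path.exists():
            pos_df = pd.read_csv(pos_path)
            positions = pos_df[["x_um", "y_um"]].to_numpy(dtype=float)
            if "label" in pos_df.columns:
                labels = list(pos_df["label"])
        else:
            positions = np.zeros((traces.shape[1], 2))
        return FluorescenceRecording(
            traces=traces.to_numpy(dtype=float),
            fs_hz=fs,
            positions=positions,
            roi_ids=[str(c) for c in traces.columns],
            labels=labels,
        )
    raise ValueError(f"unknown format {fmt!r}")


def save_ground_truth(truth: SyntheticGroundTruth, prefix: str | Path) -> None:
    """Write planted truth: edge list, module labels, spike events (CSV)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    src, dst = np.nonzero(truth.adjacency)
    pd.DataFrame({"src": src, "dst": dst}).to_csv(
        f"{prefix}.edges.csv", index=False
    )
    pd.DataFrame(
        {
            "neuron_id": np.arange(truth.module_labels.size),
            "module": truth.module_labels,
        }
    ).to_csv(f"{prefix}.modules.csv", index=False)
    rows = [
        (i, t) for i, times in enumerate(truth.spike_times) for t in times
    ]
    pd.DataFrame(rows, columns=["neuron_id", "time_s"]).to_csv(
        f"{prefix}.spikes.csv", index=False
    )


def load_ground_truth_adjacency(prefix: str | Path, n: int) -> np.ndarray:
    edges = pd.read_csv(f"{Path(prefix)}.edges.csv")
    a = np.zeros((n, n), dtype=np.uint8)
    a[edges["src"].to_numpy(), edges["dst"].to_numpy()] = 1
    return a


def save_event_list(
    onsets: list[np.ndarray], roi_ids: list[str], path: str | Path
) -> None:
    rows = [
        (roi_ids[i], t) for i, times in enumerate(onsets) for t in times
    ]
    pd.DataFrame(rows, columns=["roi_id", "time_s"]).to_csv(path, index=False)


def load_event_list(
    path: str | Path, roi_ids: list[str]
) -> list[np.ndarray]:
    df = pd.read_csv(path)
    by_roi = {rid: [] for rid in roi_ids}
    for rid, t in zip(df["roi_id"], df["time_s"]):
        by_roi[str(rid)].append(float(t))
    return [np.sort(np.asarray(by_roi[rid])) for rid in roi_ids]


def save_matrix(matrix: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(matrix), delimiter=",", fmt="%.12g")


def load_matrix(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
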