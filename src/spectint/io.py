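"""HDF5 dataset container and table export.

Layout::

    /traces        float array (roi x trial x frame), dF/F
    /schedule/*    trial table columns (trial, block, condition_id, ...)
    /conditions/*  condition table columns
    /ground_truth  optional per-cell truth (li_kernel stack, amplitudes)

Attributes on the root group record frame rate, onset frame and the
generator seed.  The schedule is also exportable as CSV.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .traces import RoiTraceSet


def _write_frame(group: h5py.Group, df: pd.DataFrame) -> None:
    for col in df.columns:
        data = df[col].to_numpy()
        if data.dtype == object:
            data = data.astype(str)
            group.create_dataset(col, data=np.char.encode(data, "utf-8"))
        else:
            group.create_dataset(col, data=data)
    group.attrs["columns"] = json.dumps(list(df.columns))


def _read_frame(group: h5py.Group) -> pd.DataFrame:
    cols = json.loads(group.attrs["columns"])
    out = {}
    for col in cols:
        data = group[col][()]
        if data.dtype.kind == "S":
            data = np.char.decode(data, "utf-8")
        out[col] = data
    return pd.DataFrame(out)


def save_dataset(path, ts: RoiTraceSet, ground_truth=None,
                 seed: int | None = None) -> None:
    """Write a trial-aligned dataset (and optional ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=ts.dff, compression="gzip")
        f.attrs["frame_rate"] = ts.frame_rate
        f.attrs["onset_frame"] = ts.onset_frame
        if seed is not None:
            f.attrs["seed"] = seed
        _write_frame(f.create_group("schedule"), ts.trials)
        _write_frame(f.create_group("conditions"), ts.conditions)
        f.create_dataset("roi_ids", data=np.asarray(ts.roi_ids))
        if ground_truth is not None:
            g = f.create_group("ground_truth")
            g.create_dataset("li_kernel",
                             data=np.stack([c.li_kernel for c in ground_truth]))
            g.create_dataset("base_amp_center",
                             data=[c.base_amp_center for c in ground_truth])


def load_dataset(path) -> RoiTraceSet:
    """Read a dataset container back into a :class:`RoiTraceSet`."""
    with h5py.File(path, "r") as f:
        ts = RoiTraceSet(
            dff=f["traces"][()],
            onset_frame=int(f.attrs["onset_frame"]),
            frame_rate=float(f.attrs["frame_rate"]),
            trials=_read_frame(f["schedule"]),
            conditions=_read_frame(f["conditions"]),
            roi_ids=f["roi_ids"][()],
        )
    return ts


def load_ground_truth_kernels(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        if "ground_truth" not in f:
            raise KeyError("dataset carries no ground truth")
        return f["ground_truth/li_kernel"][()]


def export_schedule_csv(path, ts: RoiTraceSet) -> None:
    sched = ts.trials.merge(ts.conditions, on="condition_id", how="left")
    sched.to_csv(path, index=False)
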