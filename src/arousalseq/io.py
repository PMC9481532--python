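"""Readers and writers for the plain-text session formats.

All tabular data are tab-separated values.  Events follow the BIDS
``events.tsv`` convention (columns ``onset``, ``duration``, ``trial_type``).
Physiological waveforms are a TSV table with a JSON sidecar holding the
sampling rate and start time.  Writers prepend ``# key: value`` comment lines
as a provenance block; readers skip any leading ``#`` lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import FormatError, ROITimeseries, SampledSeries


def _provenance_header(provenance: Mapping | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_tsv(path, df: pd.DataFrame, provenance: Mapping | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_header(provenance))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_roi_table(path, rois: list[ROITimeseries], provenance: Mapping | None = None) -> None:
    """Write ROI traces as a table with a leading ``time`` column (seconds)."""
    if not rois:
        raise FormatError("no ROI series to write")
    t = rois[0].times
    data = {"time": t}
    for roi in rois:
        if roi.series.n != t.size:
            raise FormatError(f"ROI {roi.name!r} length differs from time axis")
        data[roi.name] = roi.values
    write_tsv(path, pd.DataFrame(data), provenance)


def read_roi_table(path) -> list[ROITimeseries]:
    df = read_tsv(path)
    if "time" not in df.columns:
        raise FormatError("ROI table must have a 'time' column")
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError("ROI table needs at least two samples")
    dt = float(np.median(np.diff(t)))
    out = []
    for col in df.columns:
        if col == "time":
            continue
        series = SampledSeries(df[col].to_numpy(dtype=float), start=float(t[0]), dt=dt)
        out.append(ROITimeseries(name=col, series=series, tr=dt))
    return out


def write_events(path, onsets, trial_types, durations=None, provenance: Mapping | None = None) -> None:
    onsets = np.asarray(onsets, dtype=float)
    if durations is None:
        durations = np.zeros_like(onsets)
    df = pd.DataFrame(
        {"onset": onsets, "duration": np.asarray(durations, dtype=float), "trial_type": list(trial_types)}
    )
    write_tsv(path, df, provenance)


def read_events(path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = {"onset", "trial_type"} - set(df.columns)
    if missing:
        raise FormatError(f"events table missing columns: {sorted(missing)}")
    return df


def write_physio(path_tsv, path_json, cardiac, respiratory, fs: float, start: float = 0.0,
                 provenance: Mapping | None = None) -> None:
    df = pd.DataFrame({"cardiac": np.asarray(cardiac, float), "respiratory": np.asarray(respiratory, float)})
    write_tsv(path_tsv, df, provenance)
    with open(path_json, "w") as fh:
        json.dump({"SamplingFrequency": fs, "StartTime": start}, fh, indent=1)


def read_physio(path_tsv, path_json):
    """Return (cardiac, respiratory, fs, start)."""
    df = read_tsv(path_tsv)
    with open(path_json) as fh:
        meta = json.load(fh)
    return (
        df["cardiac"].to_numpy(dtype=float),
        df["respiratory"].to_numpy(dtype=float),
        float(meta["SamplingFrequency"]),
        float(meta.get("StartTime", 0.0)),
    )


def write_motion(path, params: np.ndarray, tr: float, provenance: Mapping | None = None) -> None:
    """Write 6-column rigid-body parameters (3 translations mm, 3 rotations rad)."""
    params = np.asarray(params, float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise FormatError("motion parameters must have 6 columns")
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    prov = dict(provenance or {})
    prov["tr"] = tr
    write_tsv(path, pd.DataFrame(params, columns=cols), prov)


def read_motion(path) -> np.ndarray:
    df = read_tsv(path)
    if df.shape[1] != 6:
        raise FormatError(f"motion file must have 6 columns, found {df.shape[1]}")
    return df.to_numpy(dtype=float)


def write_json(path, obj, provenance: Mapping | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    if provenance:
        payload["provenance"] = dict(provenance)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
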