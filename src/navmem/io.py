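"""Text and HDF5 persistence for sessions, montages, recordings and power."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .spectral import PowerTensor
from .synthetic import (
    MONTAGE_COLUMNS,
    ArenaConfig,
    Recording,
    TaskConfig,
    TaskSession,
)

__all__ = [
    "write_session_tsv",
    "read_session_tsv",
    "write_montage_tsv",
    "read_montage_tsv",
    "write_recording_h5",
    "read_recording_h5",
    "write_power_h5",
    "read_power_h5",
]

_EVENT_COLS = [
    "event",
    "trial",
    "onset_ms",
    "offset_ms",
    "x",
    "y",
    "object_id",
    "remembered",
]


def write_session_tsv(session: TaskSession, events_path, responses_path) -> None:
    ev = session.events.reindex(columns=_EVENT_COLS)
    ev.to_csv(events_path, sep="\t", index=False)
    session.responses.to_csv(responses_path, sep="\t", index=False)


def read_session_tsv(
    events_path,
    responses_path,
    arena: ArenaConfig | None = None,
    task: TaskConfig | None = None,
    subject: str = "S00",
) -> TaskSession:
    ev = pd.read_csv(events_path, sep="\t")
    ev["object_id"] = ev["object_id"].astype("Int64")
    resp = pd.read_csv(responses_path, sep="\t")
    duration = float(ev["offset_ms"].max()) + 6000.0
    return TaskSession(
        events=ev,
        responses=resp,
        arena=arena or ArenaConfig(),
        task=task or TaskConfig(),
        duration_ms=duration,
        subject=subject,
    )


def write_montage_tsv(montage: pd.DataFrame, path) -> None:
    montage.reindex(columns=MONTAGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_montage_tsv(path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t")
    m["soz"] = m["soz"].astype(bool)
    return m


def write_recording_h5(recording: Recording, path, ground_truth: dict | None = None) -> None:
    """Recording as HDF5: data matrix + montage columns + optional sidecar.

    ``ground_truth`` (e.g. the NeuralModel parameters) is stored alongside
    and also written to a JSON sidecar next to the file.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data, compression="gzip")
        f.attrs["fs"] = recording.fs
        g = f.create_group("montage")
        for col in recording.montage.columns:
            vals = recording.montage[col].to_numpy()
            if vals.dtype == object:
                # stringify non-scalar metadata (e.g. parent-contact tuples)
                vals = np.array([str(v) for v in vals], dtype="S")
            g.create_dataset(col, data=vals)
        if ground_truth is not None:
            f.attrs["ground_truth"] = json.dumps(ground_truth)
    if ground_truth is not None:
        path.with_suffix(".json").write_text(json.dumps(ground_truth, indent=2))


def read_recording_h5(path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs = float(f.attrs["fs"])
        cols = {}
        for col, ds in f["montage"].items():
            vals = ds[()]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            cols[col] = vals
    # column order is cosmetic; row order must match the data rows, so no sort
    montage = pd.DataFrame(cols)
    lead = [c for c in ("channel", "probe", "contact") if c in montage]
    montage = montage[lead + [c for c in montage.columns if c not in lead]]
    return Recording(data=data, fs=fs, montage=montage)


def write_power_h5(power: PowerTensor, path) -> None:
    """PowerTensor with dimension labels and provenance attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=power.values, compression="gzip")
        f.create_dataset("freqs", data=power.freqs)
        f.attrs["scale"] = power.scale
        f.attrs["grouping"] = json.dumps(list(power.grouping))
        f.attrs["dims"] = json.dumps(
            ["event", "channel", "frequency"]
            + (["time_bin"] if power.time_bins_ms is not None else [])
        )
        if power.time_bins_ms is not None:
            f.create_dataset("time_bins_ms", data=power.time_bins_ms)
        f.create_dataset(
            "events_json", data=np.bytes_(power.events.to_json(orient="table"))
        )
        f.create_dataset(
            "channels_json", data=np.bytes_(power.channels.to_json(orient="table"))
        )


def read_power_h5(path) -> PowerTensor:
    with h5py.File(path, "r") as f:
        import io as _io

        return PowerTensor(
            values=f["values"][()],
            freqs=f["freqs"][()],
            events=pd.read_json(_io.BytesIO(f["events_json"][()]), orient="table"),
            channels=pd.read_json(_io.BytesIO(f["channels_json"][()]), orient="table"),
            scale=str(f.attrs["scale"]),
            time_bins_ms=f["time_bins_ms"][()] if "time_bins_ms" in f else None,
            grouping=tuple(json.loads(f.attrs["grouping"])),
        )
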