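"""Readers and writers for recordings and analysis tables.

Recordings travel as HDF5 (datasets ``/channels/<label>``, root attributes
``fs``, ``t0``, ``channel_order``) or as flat CSV whose first line is a
metadata comment (``# fs=10000.0 t0=0.0``) followed by ``time`` and one
column per channel. Event and result tables are plain CSV; stimulation
protocols are a CSV of pulse onsets plus a YAML metadata sidecar.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .bursts import Burst, FEATURE_NAMES
from .detect import SpikeTrain
from .recording import LFPRecording, StimulationProtocol


def _check_finite(rec: LFPRecording) -> None:
    bad = [lab for lab, row in zip(rec.channel_labels, rec.samples)
           if not np.all(np.isfinite(row))]
    if bad:
        raise ValueError(f"non-finite samples in channel(s): {bad}")


def write_recording_h5(rec: LFPRecording, path: str | Path) -> None:
    _check_finite(rec)
    with h5py.File(path, "w") as f:
        g = f.create_group("channels")
        for lab, row in zip(rec.channel_labels, rec.samples):
            g.create_dataset(lab, data=row)
        f.attrs["fs"] = rec.fs
        f.attrs["t0"] = rec.t0
        f.attrs["channel_order"] = [s.encode() for s in rec.channel_labels]


def write_recording_csv(rec: LFPRecording, path: str | Path) -> None:
    _check_finite(rec)
    df = pd.DataFrame({"time": rec.times()})
    for lab, row in zip(rec.channel_labels, rec.samples):
        df[lab] = row
    with open(path, "w") as f:
        f.write(f"# fs={rec.fs} t0={rec.t0}\n")
        df.to_csv(f, index=False)


def read_recording(path: str | Path, fmt: str | None = None) -> LFPRecording:
    """Read a recording from HDF5 or metadata-commented CSV.

    The format is inferred from the extension unless given; a CSV without
    the ``# fs=...`` metadata line is rejected.
    """
    path = Path(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            if "fs" not in f.attrs:
                raise ValueError(f"{path}: missing fs attribute")
            order = [s.decode() if isinstance(s, bytes) else str(s)
                     for s in f.attrs.get("channel_order",
                                          list(f["channels"].keys()))]
            samples = np.vstack([f["channels"][lab][()] for lab in order])
            rec = LFPRecording(samples, float(f.attrs["fs"]), order,
                               float(f.attrs.get("t0", 0.0)))
    elif fmt == "csv":
        with open(path) as f:
            first = f.readline()
            if not first.startswith("#") or "fs=" not in first:
                raise ValueError(f"{path}: missing '# fs=...' metadata line")
            meta = dict(kv.split("=") for kv in first[1:].split())
            df = pd.read_csv(f)
        labels = [c for c in df.columns if c != "time"]
        rec = LFPRecording(df[labels].to_numpy().T, float(meta["fs"]),
                           labels, float(meta.get("t0", 0.0)))
    else:
        raise ValueError(f"unknown recording format {fmt!r}")
    _check_finite(rec)
    return rec


def write_protocol(protocol: StimulationProtocol, csv_path: str | Path) -> None:
    """Pulse onsets as CSV plus a YAML sidecar with the metadata."""
    csv_path = Path(csv_path)
    pd.DataFrame({"onset_s": protocol.pulse_times}).to_csv(csv_path,
                                                           index=False)
    meta = {"pulse_duration_s": float(protocol.pulse_duration),
            "frequency_hz": (None if protocol.frequency is None
                             else float(protocol.frequency)),
            "modality": protocol.modality}
    csv_path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def read_protocol(csv_path: str | Path) -> StimulationProtocol:
    csv_path = Path(csv_path)
    onsets = pd.read_csv(csv_path)["onset_s"].to_numpy()
    sidecar = csv_path.with_suffix(".yaml")
    meta = yaml.safe_load(sidecar.read_text()) if sidecar.exists() else {}
    return StimulationProtocol(
        onsets, float(meta.get("pulse_duration_s", 0.05)),
        meta.get("frequency_hz"), meta.get("modality", "optical"))


def write_boundaries(boundaries: pd.DataFrame, path: str | Path) -> None:
    boundaries.to_csv(path, index=False)


def read_boundaries(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"label", "start_s", "end_s"} - set(df.columns)
    if missing:
        raise ValueError(f"boundaries table missing columns {sorted(missing)}")
    return df


def write_spikes(train: SpikeTrain, path: str | Path) -> None:
    pd.DataFrame({"time_s": train.times, "amplitude": train.amplitudes,
                  "source": train.source}).to_csv(path, index=False)


def read_spikes(path: str | Path) -> SpikeTrain:
    df = pd.read_csv(path)
    return SpikeTrain(df["time_s"].to_numpy(), df["amplitude"].to_numpy(),
                      df["source"].to_numpy(dtype=object))


def write_bursts(bursts: list[Burst], path: str | Path) -> None:
    rows = []
    for b in bursts:
        feats = (b.features if b.features is not None
                 else [np.nan] * len(FEATURE_NAMES))
        rows.append({"start_s": b.start_s, "end_s": b.end_s,
                     "n_spikes": b.n_spikes,
                     **dict(zip(FEATURE_NAMES, feats)),
                     "class": b.label if b.label else "unclassified"})
    pd.DataFrame(rows, columns=["start_s", "end_s", "n_spikes",
                                *FEATURE_NAMES, "class"]).to_csv(path,
                                                                 index=False)


def read_bursts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
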