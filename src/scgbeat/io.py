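"""Record readers and writers.

Two on-disk layouts are supported:

* ``csv`` — one column per channel with a header row of labels, plus a JSON
  sidecar (same stem, ``.json``) that names the sampling rate and the ECG
  column. Round-trips losslessly.
* ``wfdb`` — PhysioNet waveform-database records (``.hea`` header plus a
  format-16 ``.dat``), the layout the CEBS database ("cebsdb") is
  distributed in. Only the single-segment, format-16, single-dat-file case
  is handled, which covers CEBS.

SCG columns are labelled ``patch<k>_<axis>``; the ECG column label is stated
in the sidecar (default ``"ecg"``). A WFDB "SCG" signal with merged axes is
mapped to ``patch0_combined``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .signals import ChannelId, PeakTrain, SyncRecord, WaveSignal

__all__ = [
    "read_record",
    "write_record",
    "save_peaks",
    "load_peaks",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_csv_record(path: Path) -> SyncRecord:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar config {sidecar}")
    cfg = json.loads(sidecar.read_text())
    fs = float(cfg["fs"])
    ecg_label = cfg.get("ecg_label", "ecg")
    df = pd.read_csv(path, float_precision="round_trip")  # lossless round-trip
    if ecg_label not in df.columns:
        raise ValueError(
            f"no ECG reference channel: column {ecg_label!r} absent from {path.name}"
        )
    ecg = WaveSignal(df[ecg_label].to_numpy(float), fs, ecg_label)
    scg: Dict[ChannelId, WaveSignal] = {}
    for col in df.columns:
        if col == ecg_label:
            continue
        cid = ChannelId.parse(col)
        scg[cid] = WaveSignal(df[col].to_numpy(float), fs, col)
    if not scg:
        raise ValueError(f"no SCG channels found in {path.name}")
    return SyncRecord(ecg=ecg, scg=scg, fs=fs)


def _parse_hea(path: Path):
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_line = lines[0].split()
    name, nsig = rec_line[0], int(rec_line[1])
    fs = float(rec_line[2]) if len(rec_line) > 2 else 250.0
    sig_specs = []
    for ln in lines[1 : 1 + nsig]:
        parts = ln.split()
        fname, fmt = parts[0], parts[1]
        gain, baseline, units = 200.0, 0, ""
        if len(parts) > 2:
            g = parts[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, base = g.split("(", 1)
                baseline = int(base.rstrip(")"))
            gain = float(g) if g else 200.0
        desc = " ".join(parts[8:]) if len(parts) > 8 else fname
        sig_specs.append(
            {"file": fname, "fmt": fmt, "gain": gain, "baseline": baseline,
             "units": units, "desc": desc}
        )
    return name, nsig, fs, sig_specs


def _read_wfdb_record(path: Path) -> SyncRecord:
    """Read a single-segment format-16 WFDB record (.hea + .dat)."""
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    name, nsig, fs, specs = _parse_hea(hea)
    fmts = {s["fmt"].split("+")[0] for s in specs}
    if fmts != {"16"}:
        raise ValueError(f"only WFDB format 16 is supported, got {sorted(fmts)}")
    dat_files = {s["file"] for s in specs}
    if len(dat_files) != 1:
        raise ValueError("multi-file WFDB records are not supported")
    dat = hea.parent / next(iter(dat_files))
    raw = np.fromfile(dat, dtype="<i2")
    n = raw.size // nsig
    raw = raw[: n * nsig].reshape(n, nsig)

    ecg = None
    scg: Dict[ChannelId, WaveSignal] = {}
    patch_counter = 0
    for k, spec in enumerate(specs):
        phys = (raw[:, k].astype(float) - spec["baseline"]) / spec["gain"]
        desc = spec["desc"].strip()
        low = desc.lower()
        sig = WaveSignal(phys, fs, desc)
        if low == "i" or low.startswith("ecg"):
            if ecg is None:  # lead I is listed first in CEBS headers
                ecg = sig
        elif low == "ii":
            continue  # lead II unused (lead I is the reference)
        elif "scg" in low or "accel" in low:
            axis = low.rsplit("_", 1)[-1] if low[-2:] in ("_x", "_y", "_z") else "combined"
            cid = ChannelId(patch_counter, axis)
            if axis == "combined":
                patch_counter += 1
            scg[cid] = sig
    if ecg is None:
        raise ValueError(f"no ECG reference channel in record {name}")
    if not scg:
        raise ValueError(f"no SCG channel in record {name}")
    return SyncRecord(ecg=ecg, scg=scg, fs=fs)


def read_record(path: str | Path, format: str = "csv") -> SyncRecord:
    """Read a time-aligned ECG + SCG record.

    Parameters
    ----------
    path : path
        CSV file (with JSON sidecar) or WFDB record path/``.hea`` file.
    format : {"csv", "wfdb"}
    """
    path = Path(path)
    if format == "csv":
        return _read_csv_record(path)
    if format == "wfdb":
        return _read_wfdb_record(path)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'wfdb'")


def write_record(rec: SyncRecord, path: str | Path) -> Path:
    """Write a record as CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    ecg_label = rec.ecg.label or "ecg"
    cols = {ecg_label: rec.ecg.samples}
    for cid in rec.channels:
        cols[str(cid)] = rec.scg[cid].samples
    pd.DataFrame(cols).to_csv(path, index=False)
    _sidecar_path(path).write_text(
        json.dumps({"fs": rec.fs, "ecg_label": ecg_label}, indent=2)
    )
    return path


def save_peaks(train: PeakTrain, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"fs": train.fs, "indices": train.indices.tolist()})
    )


def load_peaks(path: str | Path) -> PeakTrain:
    obj = json.loads(Path(path).read_text())
    return PeakTrain(np.asarray(obj["indices"], dtype=np.int64), float(obj["fs"]))
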