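"""Recording and cohort I/O.

The internal container stores one recording as a ``.npy`` payload (channels x
samples, µV) next to a JSON text header carrying channel names, sampling
rate and marker sample indices.  Cohorts are one directory per subject plus
a cohort-level TSV of clinical covariates.  BrainVision (.vhdr/.vmrk/.eeg)
and EDF files are read through MNE with markers taken from stimulus/
annotation events; a minimal BrainVision writer (IEEE float 32, multiplexed)
is provided for round-trip testing.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .preprocess import Recording


# ---------------------------------------------------------------------------
# internal container
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, path) -> None:
    """Write ``<path>.npy`` (payload) and ``<path>.json`` (text header)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), rec.data)
    header = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "markers": [int(m) for m in rec.markers],
        "units": "uV",
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))


def load_recording(path) -> Recording:
    path = Path(path)
    data = np.load(path.with_suffix(".npy"))
    header = json.loads(path.with_suffix(".json").read_text())
    return Recording(data=data, fs=header["fs"],
                     channel_names=header["channel_names"],
                     markers=np.asarray(header["markers"], dtype=int))


def save_cohort(records: list[SubjectRecord], root) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        d = root / rec.subject_id
        d.mkdir(exist_ok=True)
        save_recording(rec.resting, d / "resting")
        save_recording(rec.tms, d / "tms")
        rows.append({"subject_id": rec.subject_id, "group": rec.group,
                     "age": rec.age, "MADRS": rec.madrs,
                     "STAI_state": rec.stai_state, "STAI_trait": rec.stai_trait,
                     "MMSE": rec.mmse})
    pd.DataFrame(rows).to_csv(root / "covariates.tsv", sep="\t", index=False)


def load_cohort(root) -> list[SubjectRecord]:
    root = Path(root)
    cov = pd.read_csv(root / "covariates.tsv", sep="\t")
    records = []
    for _, row in cov.iterrows():
        d = root / row["subject_id"]
        records.append(SubjectRecord(
            subject_id=row["subject_id"], group=row["group"], age=row["age"],
            madrs=row["MADRS"], stai_state=row["STAI_state"],
            stai_trait=row["STAI_trait"], mmse=row["MMSE"],
            resting=load_recording(d / "resting"), tms=load_recording(d / "tms"),
        ))
    return records


# ---------------------------------------------------------------------------
# BrainVision / EDF
# ---------------------------------------------------------------------------

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval_us}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channel_lines}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
Mk1=New Segment,,1,1,0
{marker_lines}
"""


def write_brainvision(rec: Recording, path) -> Path:
    """Minimal BrainVision triplet (IEEE float 32, multiplexed, µV)."""
    path = Path(path)
    stem = path.stem
    ch_lines = "\n".join(
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(rec.channel_names)
    )
    mk_lines = "\n".join(
        f"Mk{i + 2}=Stimulus,S  1,{int(m) + 1},1,0"
        for i, m in enumerate(rec.markers)
    )
    vhdr = _VHDR_TEMPLATE.format(
        stem=stem, n_channels=len(rec.channel_names),
        sampling_interval_us=int(round(1e6 / rec.fs)), channel_lines=ch_lines,
    )
    path.with_suffix(".vhdr").write_text(vhdr, encoding="utf-8")
    path.with_suffix(".vmrk").write_text(
        _VMRK_TEMPLATE.format(stem=stem, marker_lines=mk_lines), encoding="utf-8"
    )
    rec.data.T.astype("<f4").tofile(path.with_suffix(".eeg"))
    return path.with_suffix(".vhdr")


def read_recording(path, format: str = "internal") -> Recording:
    """Read a recording from the internal container, BrainVision or EDF.

    Data are returned in µV; markers come from .vmrk stimulus entries
    (BrainVision) or annotations (EDF).
    """
    path = Path(path)
    if format == "internal":
        return load_recording(path)
    if format not in ("brainvision", "edf"):
        raise ValueError(f"unknown format {format!r}")

    import mne

    try:
        if format == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"failed to parse {format} file {path}: {exc}") from exc
    data = raw.get_data() * 1e6            # MNE works in volts
    fs = float(raw.info["sfreq"])
    markers = []
    for ann in raw.annotations:
        desc = str(ann["description"])
        if "Stimulus" in desc or desc.startswith("S"):
            markers.append(int(round(ann["onset"] * fs)))
    return Recording(data=data, fs=fs, channel_names=list(raw.ch_names),
                     markers=np.asarray(sorted(set(markers)), dtype=int))


def require_markers(rec: Recording) -> Recording:
    if rec.markers.size == 0:
        raise ValueError("recording carries no markers; the TMS pipeline "
                         "requires stimulation events")
    return rec
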