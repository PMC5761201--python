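"""Plain-text persistence for recordings and feature matrices.

A subject is written as one directory containing one two-column numeric
text file per channel (time_s, value) and a JSON sidecar with the
subject id, per-channel sampling rates and units, and the protocol
marks. Feature matrices are tab-separated tables with a JSON header
sidecar; round-trips are bit-exact (floats serialized at full
precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .synthetic import ChannelSignal, ProtocolMarks, SubjectRecording

__all__ = [
    "write_subject",
    "read_subject",
    "write_feature_matrix",
    "read_feature_matrix",
]

_CHANNELS = ("bp", "fv", "o2hb", "hhb", "etco2", "ti")


def write_subject(rec: SubjectRecording, out_dir: str | Path) -> Path:
    """Write one recording to a directory; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "subject_id": rec.subject_id,
        "marks": {
            "t_baseline_start": rec.marks.t_baseline_start,
            "t_lbnp_onset": rec.marks.t_lbnp_onset,
            "t_presyncope": rec.marks.t_presyncope,
        },
        "channels": {},
    }
    for name in _CHANNELS:
        ch: ChannelSignal = getattr(rec, name)
        t = ch.times()
        data = np.column_stack([t, ch.samples])
        np.savetxt(out / f"{name}.tsv", data, fmt="%.17g", delimiter="\t",
                   header="time_s\tvalue", comments="")
        meta["channels"][name] = {"fs": ch.fs, "units": ch.units,
                                  "n_samples": int(ch.samples.size)}
    (out / "subject.json").write_text(json.dumps(meta, indent=1))
    return out


def read_subject(subject_dir: str | Path) -> SubjectRecording:
    """Read a recording written by :func:`write_subject`, with validation."""
    d = Path(subject_dir)
    meta = json.loads((d / "subject.json").read_text())
    marks = ProtocolMarks(**meta["marks"])
    channels = {}
    for name in _CHANNELS:
        info = meta["channels"][name]
        data = np.loadtxt(d / f"{name}.tsv", delimiter="\t", skiprows=1, ndmin=2)
        if data.shape[0] != info["n_samples"]:
            raise ValueError(f"channel {name}: sample count mismatch "
                             f"({data.shape[0]} vs {info['n_samples']})")
        samples = data[:, 1]
        expected = marks.t_presyncope * info["fs"]
        if abs(samples.size - expected) > info["fs"]:  # must cover the protocol
            raise ValueError(f"channel {name} does not cover the recording")
        channels[name] = ChannelSignal(name, samples, info["fs"], info["units"])
    return SubjectRecording(subject_id=meta["subject_id"], marks=marks, **channels)


def write_feature_matrix(fm: FeatureMatrix, prefix: str | Path) -> None:
    """Write a feature matrix as <prefix>.tsv plus <prefix>.json sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    df = fm.X.copy()
    df.insert(0, "__label", fm.y)
    df.insert(0, "__t", fm.times)
    df.insert(0, "__subject", fm.subject_ids)
    df.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False,
              float_format="%.17g")
    sidecar = {"model_id": fm.model_id, "columns": list(fm.X.columns),
               "n_samples": fm.n_samples}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_feature_matrix(prefix: str | Path) -> FeatureMatrix:
    """Inverse of :func:`write_feature_matrix`; bit-exact for finite floats."""
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t",
                     float_precision="round_trip")
    cols = sidecar["columns"]
    if list(df.columns[3:]) != cols:
        raise ValueError("feature-matrix columns do not match sidecar")
    return FeatureMatrix(
        X=df[cols].astype(float),
        y=df["__label"].to_numpy(dtype=int),
        subject_ids=df["__subject"].to_numpy(),
        times=df["__t"].to_numpy(dtype=float),
        model_id=int(sidecar["model_id"]),
    )
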