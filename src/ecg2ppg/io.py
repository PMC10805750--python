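"""Persistence for records and segment stores.

A waveform record is written as a pair of files: ``<stem>.header.csv``
(subject id, sampling rate, rhythm label and the annotation intervals) and
``<stem>.samples.csv`` (two columns, ecg and ppg). Segment stores persist as
an ``.npz`` array container plus a CSV sidecar holding the per-segment label,
origin and parent id.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SegmentStore
from .signalsim import WaveformRecord

__all__ = ["write_record", "read_record", "write_segments", "read_segments"]


def write_record(record: WaveformRecord, out_dir: str | Path, stem: str | None = None) -> Path:
    """Write one record as a header/samples CSV pair; returns the stem path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or record.subject_id
    ann = ";".join(f"{s},{e},{r}" for s, e, r in record.annotations)
    with open(out_dir / f"{stem}.header.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "fs", "rhythm", "annotations"])
        w.writerow([record.subject_id, record.fs, record.rhythm_label, ann])
    df = pd.DataFrame({"ecg": record.ecg})
    if record.ppg is not None:
        df["ppg"] = record.ppg
    df.to_csv(out_dir / f"{stem}.samples.csv", index=False)
    return out_dir / stem


def read_record(stem: str | Path) -> WaveformRecord:
    """Read a record previously written by :func:`write_record`."""
    stem = Path(stem)
    with open(f"{stem}.header.csv", newline="") as fh:
        rows = list(csv.reader(fh))
    header = dict(zip(rows[0], rows[1]))
    annotations = []
    if header.get("annotations"):
        for part in header["annotations"].split(";"):
            s, e, r = part.split(",")
            annotations.append((int(s), int(e), r))
    df = pd.read_csv(f"{stem}.samples.csv")
    return WaveformRecord(
        ecg=df["ecg"].to_numpy(),
        ppg=df["ppg"].to_numpy() if "ppg" in df else None,
        fs=float(header["fs"]),
        rhythm_label=header["rhythm"],
        subject_id=header["subject_id"],
        annotations=annotations,
    )


def write_segments(store: SegmentStore, path: str | Path) -> None:
    """Persist a SegmentStore as ``<path>.npz`` + ``<path>.csv`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), segments=store.segments,
             fs=store.fs, segment_seconds=store.segment_seconds,
             channels=np.array(store.channels, dtype=object))
    pd.DataFrame({
        "label": store.labels, "origin": store.origin, "parent_id": store.parent_id,
    }).to_csv(path.with_suffix(".csv"), index=False)


def read_segments(path: str | Path) -> SegmentStore:
    path = Path(path)
    with np.load(path.with_suffix(".npz"), allow_pickle=True) as npz:
        segments = npz["segments"]
        fs = float(npz["fs"])
        seconds = float(npz["segment_seconds"])
        channels = tuple(npz["channels"])
    side = pd.read_csv(path.with_suffix(".csv"))
    return SegmentStore(segments, side["label"].to_numpy(dtype=object),
                        side["origin"].to_numpy(dtype=object),
                        side["parent_id"].to_numpy(dtype=object),
                        fs, seconds, channels)
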